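gene	cdna	sample_id	status
PMS2	c.2192_2196delTAACT	10	confirmed_absent
PMS2	c.2192_2196delTAACT	21	confirmed_absent
PMS2	c.2192_2196delTAACT	22	confirmed_absent
PMS2	c.1579_1580delAG	18	confirmed_present
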