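import pytest

from crcpanel.hgvs import parse_cdna
from crcpanel.io import (AnnotationRecord, CohortTable, Location,
                         load_fixture, parse_clinvar, parse_maf)
from crcpanel.panel import default_panel
from crcpanel.pipeline import run_pipeline
from crcpanel.simulate import paper_scenario


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def table3_records(panel):
    """The 28 candidate-pathogenic carrier rows as annotation records."""
    records = []
    for _, row in load_fixture("table3_pgv").iterrows():
        v = parse_cdna(row["cdna"], gene=row["gene"], protein=row["protein"])
        records.append(AnnotationRecord(
            sample_id=str(row["patient_id"]), gene=row["gene"],
            transcript=panel[row["gene"]].refseq, hgvs=v,
            location=(Location.FLANKING if v.intron_offset is not None
                      else Location.EXONIC),
            filter_status="PASS", depth=604,
            maf=parse_maf(row["maf"]), clinvar=parse_clinvar(row["clinvar"])))
    return records


@pytest.fixture(scope="session")
def scenario():
    return paper_scenario()


@pytest.fixture(scope="session")
def scenario_result(scenario):
    return run_pipeline(scenario.cohort, curated=scenario.curated,
                        ledger=scenario.ledger,
                        reported_flags=scenario.reported_flags)


def make_record(sample_id="S1", gene="MSH2", cdna="c.100C>T",
                protein="p.Gln34Ter", location=Location.EXONIC,
                filter_status="PASS", depth=604, maf=None,
                clinvar="no_entry", predictions=None):
    """Terse builder for hand-made funnel inputs."""
    from crcpanel.io import ClinVar
    return AnnotationRecord(
        sample_id=sample_id, gene=gene, transcript="NM_000000.0",
        hgvs=parse_cdna(cdna, gene=gene, protein=protein),
        location=location, filter_status=filter_status, depth=depth,
        maf=maf, clinvar=ClinVar(clinvar),
        predictions=predictions or {})
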