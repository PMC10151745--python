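from types import SimpleNamespace

import pandas as pd
import pytest

from floramap import cluster, readproc, synthio, taxassign


@pytest.fixture(scope="session")
def clean_scenario():
    """Error-free reads, complete reference database: the exact-recovery regime."""
    return synthio.default_scenario(seed=11, n_sites=12, reads_per_sample=60,
                                    error_rate=0.0, fail_fraction=0.0)


@pytest.fixture(scope="session")
def cleaned_batch(clean_scenario, tmp_path_factory):
    out = tmp_path_factory.mktemp("fastq")
    r1, r2 = out / "R1.fastq", out / "R2.fastq"
    synthio.write_fastq(clean_scenario.fwd_records, r1)
    synthio.write_fastq(clean_scenario.rev_records, r2)
    manifest = pd.DataFrame({
        "sample": clean_scenario.landscape.site_ids,
        "barcode": [clean_scenario.barcode_map[s]
                    for s in clean_scenario.landscape.site_ids],
    })
    cleaned, report = readproc.clean_batch(r1, r2, manifest)
    return SimpleNamespace(cleaned=cleaned, report=report, manifest=manifest,
                           r1=r1, r2=r2)


@pytest.fixture(scope="session")
def otu_result(cleaned_batch):
    reads = [(r.read_id, r.sample, r.sequence) for r in cleaned_batch.cleaned]
    return cluster.greedy_cluster(reads)


@pytest.fixture(scope="session")
def assignments(otu_result, clean_scenario):
    hits = taxassign.search_internal(dict(otu_result.centroids), clean_scenario.refdb)
    return taxassign.assign_all(hits)
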