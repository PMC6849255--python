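"""Shared fixtures: a toy genome, the default promoter model, and one
session-scoped study-scale synthetic dataset reused by the expensive tests."""

from __future__ import annotations

import pytest

from promine.genome_io import Gene
from promine.pipeline import RunConfig, run_mine
from promine.promoter_scan import build_default_model
from promine.synthetic import study_scale_fixture

FIXTURE_SEED = 20260927


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture()
def toy_genome():
    """A 2-gene toy contig: one gene per strand, generous upstream room."""
    filler = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(4000))
    contig = bytearray(filler.encode())
    contig[1000:1003] = b"ATG"  # start codon of the + gene
    contig[3397:3400] = b"CAT"  # start codon of the - gene (reverse complement)
    contig = contig.decode()
    genes = [
        Gene("gplus", "chr", 1000, 2000, "+", product="Ferritin"),
        Gene("gminus", "chr", 2600, 3400, "-", product="Molecular chaperone DnaK"),
    ]
    return genes, {"chr": contig}


@pytest.fixture(scope="session")
def study_dataset():
    return study_scale_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def study_run(study_dataset, tmp_path_factory):
    """The study-scale dataset written to disk and mined end to end."""
    root = tmp_path_factory.mktemp("study_scale")
    paths = study_dataset.write(root / "data")
    config = RunConfig(
        fasta=paths["fasta"],
        gff=paths["gff"],
        counts_a=paths["counts_a"],
        counts_b=paths["counts_b"],
        outdir=root / "run",
    )
    result = run_mine(config)
    return study_dataset, paths, config, result
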