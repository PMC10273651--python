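"""Shared fixtures: a hand-built two-gene toy locus and a session-scoped
default synthetic dataset (seed 1)."""

from __future__ import annotations

import pytest

from circsam.genome import GeneModel, Genome, Interval
from circsam.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def sim_default(tmp_path_factory):
    """Default synthetic dataset, seed 1."""
    outdir = tmp_path_factory.mktemp("sim_seed1")
    return generate_dataset(SimConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def pipeline_config(sim_default):
    """Pipeline input mapping for the default synthetic dataset."""
    p = sim_default.paths
    return {
        "inputs": {
            "genome": str(p["genome"]),
            "annotation": str(p["annotation"]),
            "calls": str(p["calls_dir"]),
            "counts": str(p["counts"]),
            "design": str(p["design"]),
            "mirnas": str(p["mirnas"]),
            "transcripts": str(p["transcripts"]),
            "go_map": str(p["go_map"]),
            "go_terms": str(p["go_terms"]),
        },
        "params": {"seed": 11, "controls_n": 60},
    }


@pytest.fixture()
def toy_genome():
    # Chr1: plus-strand 3-exon gene; Chr2: minus-strand 3-exon gene
    return Genome(
        {
            "Chr1": "".join("ACGT" for _ in range(300)),  # 1200 nt
            "Chr2": "".join("GATTCCA" for _ in range(200)),  # 1400 nt
        }
    )


@pytest.fixture()
def toy_genes():
    plus = GeneModel(
        gene_id="gplus",
        chromosome="Chr1",
        strand="+",
        exons=[
            Interval("Chr1", 100, 200, "+"),
            Interval("Chr1", 300, 400, "+"),
            Interval("Chr1", 500, 600, "+"),
        ],
    )
    minus = GeneModel(
        gene_id="gminus",
        chromosome="Chr2",
        strand="-",
        # transcription order = descending genomic coordinate
        exons=[
            Interval("Chr2", 900, 1000, "-"),
            Interval("Chr2", 600, 700, "-"),
            Interval("Chr2", 300, 400, "-"),
        ],
    )
    return [plus, minus]


def sw_local_affine(a: str, b: str, match=2, mismatch=-3, open_=-5, ext=-2) -> int:
    """Exhaustive affine-gap local-alignment DP (independent oracle).

    ``open_`` is the score of the first gapped position, ``ext`` of each
    additional one; N never matches.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0
    M = [[0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            M[i][j] = max(0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + ext, Iy[i - 1][j] + open_)
            Iy[i][j] = max(M[i][j - 1] + open_, Iy[i][j - 1] + ext, Ix[i][j - 1] + open_)
            best = max(best, M[i][j])
    return best
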