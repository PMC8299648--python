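import numpy as np
import pandas as pd
import pysam
import pytest

from scapa import preprocess
from scapa.simulate import (SimCellSpec, SimGenomeSpec, make_reference,
                            simulate_counts, simulate_reads)


@pytest.fixture(scope="session")
def basic_dataset(tmp_path_factory):
    """Full simulated dataset: reference, truth counts, reads, deduped tags.

    10 two-site genes on both strands, one internal-priming decoy per gene,
    200 cells at ~30 UMIs per gene per cell — the study conditions every
    end-to-end check runs under.
    """
    outdir = tmp_path_factory.mktemp("basic")
    ref = make_reference(SimGenomeSpec(seed=1))
    cellspec = SimCellSpec(cell_types={"typeA": 200}, seed=1)
    sim = simulate_counts(cellspec, ref.sites)
    r1 = str(outdir / "r1.fastq")
    r2 = str(outdir / "r2.fastq")
    sam = str(outdir / "truth.sam")
    barcodes = simulate_reads(sim, ref, r1, r2, sam, seed=2)
    with pysam.AlignmentFile(sam) as af:
        tags = preprocess.dedup(af)
    return {"ref": ref, "sim": sim, "tags": tags, "r1": r1, "r2": r2,
            "sam": sam, "barcodes": barcodes,
            "cell_map": dict(zip(barcodes.barcode, barcodes.cell))}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_simplex(rng, n):
    v = rng.dirichlet(np.ones(n))
    return v / v.sum()
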