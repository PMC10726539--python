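"""Shared fixtures: a small seeded simulation and hand-built annotations."""

from __future__ import annotations

import pytest

from fusionval.io_formats import GeneAnnotation, GeneModel
from fusionval.simulate import (SimulationConfig, plant_fusions,
                                simulate_dataset, simulate_reference)
from fusionval.wgs_validation import prepare_alignments

#: reduced-scale simulation for unit tests (fast; the full-scale default
#: configuration is exercised by the acceptance suite)
SMALL_SIM = SimulationConfig(
    n_chromosomes=2, chrom_length=220_000, n_genes=12, n_true_fusions=4,
    fraction_intrachromosomal=0.5, base_depth=20.0, n_decoy_calls=20, seed=11)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Full simulated dataset (reference, reads, caller TSVs) at small scale."""
    out = simulate_dataset(SMALL_SIM, tmp_path_factory.mktemp("sim"))
    out["bam"] = prepare_alignments(out["paths"]["sam"])
    return out


@pytest.fixture(scope="session")
def small_reference(tmp_path_factory):
    """Reference + planted fusions only (no reads); includes a FASTA."""
    cfg = SimulationConfig(n_chromosomes=2, chrom_length=220_000, n_genes=12,
                           n_true_fusions=4, fraction_intrachromosomal=0.5,
                           seed=5)
    ref = simulate_reference(cfg)
    truths = plant_fusions(ref, cfg)
    fasta = tmp_path_factory.mktemp("ref") / "genome.fa"
    ref.write_fasta(fasta)
    return {"reference": ref, "truths": truths, "fasta": fasta,
            "config": cfg}


@pytest.fixture()
def toy_annotation():
    """Two-gene annotation with known exon/CDS structure on one chromosome."""
    g1 = GeneModel(gene_id="G1", symbol="G1", chrom="chr1", start=1000,
                   end=9000, strand="+",
                   exons=[(1000, 1400), (3000, 3400), (8600, 9000)],
                   cds_start=1200, cds_end=8800, is_kinase=True)
    g2 = GeneModel(gene_id="G2", symbol="G2", chrom="chr1", start=20_000,
                   end=30_000, strand="-",
                   exons=[(20_000, 20_500), (24_000, 24_500),
                          (29_500, 30_000)],
                   cds_start=20_250, cds_end=29_750, in_cosmic=True)
    return GeneAnnotation([g1, g2])
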