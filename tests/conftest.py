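import pytest

from rnascaf import extract_joining_pairs, scaffold_pipeline, simulate_world


@pytest.fixture(scope="session")
def default_world():
    """The standard study world: 2 x 50 kb sources, 20 four-exon genes,
    breakpoints only inside introns, 5 pairs per junction, no noise."""
    return simulate_world(seed=11)


@pytest.fixture
def run_world(tmp_path):
    """Run the full pipeline on a simulated world through real SAM/FASTA/GFF
    files; returns (PipelineResult, extraction stats)."""

    def _run(world, K=5, enforce=True, max_frac_mm=1.0, min_frac_ovl=0.0, gap_len=1000):
        paths = world.write_all(str(tmp_path / "world"))
        pairs, stats = extract_joining_pairs(paths["sam"], max_frac_mm, min_frac_ovl)
        result = scaffold_pipeline(
            world.contigs,
            world.annotations,
            pairs,
            K=K,
            gap_len=gap_len,
            enforce_reconciliation=enforce,
        )
        return result, stats

    return _run
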