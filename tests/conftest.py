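import pytest

from rhbulkseq import simulate_bulk_reads, simulate_genome, simulate_rh_panel


@pytest.fixture(scope="session")
def small_ref():
    """A 60 kb single-scaffold reference with two planted genes."""
    return simulate_genome(
        n_scaffolds=1, scaffold_len=60_000, n_genes=2, enzyme_site_spacing=2000, seed=7
    )


@pytest.fixture(scope="session")
def small_panel(small_ref):
    """64 hemizygous deletion lines over the small reference.

    Break density is scaled up so deletion segments are small relative to
    the 60 kb scaffold, as they are relative to a chromosome at full scale.
    """
    return simulate_rh_panel(small_ref, n_lines=64, breaks_per_Mb=40, seed=8)


@pytest.fixture(scope="session")
def clean_bulk(small_ref, small_panel):
    """Error-free, contaminant-free bulk reads over the small study."""
    return simulate_bulk_reads(
        small_ref, small_panel, error_rate=0.0, contam_frac=0.0, seed=6
    )


@pytest.fixture(scope="session")
def medium_ref():
    """A 1 Mb reference with six genes, for mapping-scale unit tests."""
    return simulate_genome(
        n_scaffolds=1, scaffold_len=1_000_000, n_genes=6, enzyme_site_spacing=2000, seed=9
    )
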