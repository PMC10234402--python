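import numpy as np
import pandas as pd
import pytest

from chronotopo import synthetic


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully featured synthetic configuration."""
    return synthetic.SyntheticConfig(
        seed=42,
        n_chrom=2,
        chrom_length_bp=400_000,
        telomere_copies_per_end=10,
        gap_runs=[(1, 200_000, 50)],
        n_genes_per_chrom=80,
        young_blocks=[(0, 100_000, 250_000, 8.0)],
        n_polya_reads=300,
        srna_loci_per_chrom=60,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return synthetic.generate_bundle(small_cfg, outdir)


@pytest.fixture()
def toy_lineages():
    """Five-taxon toy taxonomy with a 4-level focal ladder."""
    from chronotopo.phylostrat import TaxonLineage

    return {
        1: TaxonLineage(1, ["root", "cladeA", "genusX", "focal_sp"]),  # focal
        2: TaxonLineage(2, ["root", "cladeA", "genusX", "sister_sp"]),
        3: TaxonLineage(3, ["root", "cladeA", "genusY", "cousin_sp"]),
        4: TaxonLineage(4, ["root", "cladeB", "genusZ", "far_sp"]),
        5: TaxonLineage(5, ["root"]),
    }
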