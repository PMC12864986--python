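from __future__ import annotations

import pytest

from epromoters import Gene, make_genome


def gene(symbol: str, tss: int, chrom: str = "chr1", strand: str = "+",
         alt: tuple[int, ...] = ()) -> Gene:
    """Shorthand single-TSS gene constructor for tests."""
    all_tss = tuple(sorted({tss, *alt}))
    return Gene(symbol=symbol, chrom=chrom, strand=strand,
                canonical_tss=tss, all_tss=all_tss)


@pytest.fixture(scope="session")
def toy_genome():
    """A 2-chromosome, 800-gene toy genome shared by statistics tests."""
    return make_genome(n_chrom=2, genes_per_chrom=400, chrom_len=10_000_000,
                       min_gene_spacing=5_000, seed=42)
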