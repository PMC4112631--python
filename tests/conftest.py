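import pandas as pd
import pytest

from adjacoreg import GeneCatalogue, GeneRecord, SignedDESet


def make_catalogue(layout):
    """Build a catalogue from {chrom: [(gene_id, start, end, strand[, family]), ...]}."""
    records = []
    for chrom, genes in layout.items():
        for g in genes:
            fam = g[4] if len(g) > 4 else None
            records.append(
                GeneRecord(
                    gene_id=g[0], chromosome=chrom, start=g[1], end=g[2],
                    strand=g[3], family_id=fam,
                )
            )
    return GeneCatalogue(records)


def linear_catalogue(n, chrom="chr1", strand="+", gene_len=100, gap=50):
    """n equally spaced genes g1..gn on one chromosome."""
    genes = []
    pos = 1
    for i in range(1, n + 1):
        genes.append((f"g{i}", pos, pos + gene_len - 1, strand))
        pos += gene_len + gap
    return make_catalogue({chrom: genes})


def signed_set(signs, **kw):
    """SignedDESet from {gene_id: sign}."""
    kw.setdefault("min_abs_log2fc", 0.8)
    kw.setdefault("max_p", 0.05)
    return SignedDESet(signs=signs, **kw)


def de_frame(rows):
    """DE DataFrame from (gene_id, log2fc, p_value) tuples."""
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value"])


@pytest.fixture
def three_gene_tsv(tmp_path):
    """Shuffled 3-gene TSV annotation; sorted order is gB, gC, gA."""
    path = tmp_path / "genes.tsv"
    path.write_text(
        "gene_id\tchromosome\tstart\tend\tstrand\n"
        "gA\tchr1\t900\t1000\t+\n"
        "gB\tchr1\t100\t200\t-\n"
        "gC\tchr1\t400\t600\t+\n"
    )
    return path
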