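"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts, sample sheets, gene lengths, triplet maps and term maps are all TSV;
gene lengths may alternatively come from a GFF3 (exon lengths summed per
transcript, longest transcript per gene).
"""

from __future__ import annotations

import pandas as pd

from .containers import CountMatrix, HomeotripError, TripletMap


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountMatrix(counts, samples)


def write_counts(cm: CountMatrix, counts_path, samples_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_lengths(path) -> pd.Series:
    """Gene lengths from a two-column TSV (gene, length_bp) or a GFF3 file."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return lengths_from_gff3(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise HomeotripError("length table needs two columns: gene, length_bp")
    s = df.set_index(df.columns[0])[df.columns[1]].astype(float)
    s.name = "length_bp"
    return s


def lengths_from_gff3(path) -> pd.Series:
    """Per-gene length = summed exon length of the longest transcript.

    GFF3 coordinates are 1-based inclusive, so an exon spans end - start + 1
    bases.  Genes without annotated transcripts fall back to the gene span.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True, force=True
    )
    lengths: dict[str, float] = {}
    for gene in db.features_of_type("gene"):
        best = 0
        for tx in db.children(gene, level=1):
            exons = [f for f in db.children(tx, featuretype="exon")]
            if exons:
                best = max(best, sum(e.end - e.start + 1 for e in exons))
        if best == 0:
            best = gene.end - gene.start + 1
        lengths[gene.id] = float(best)
    return pd.Series(lengths, name="length_bp")


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene")


def read_triplets(path) -> TripletMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TripletMap(df)


def write_triplets(tmap: TripletMap, path) -> None:
    tmap.table.to_csv(path, sep="\t", index_label="anchor")


def read_term_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"}.issubset(df.columns):
        raise HomeotripError("term map needs 'gene' and 'term' columns")
    return df


def write_expression(expr, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# unit={expr.unit}\n")
        expr.values.to_csv(fh, sep="\t", index_label="gene")


def read_de(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_de(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")
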