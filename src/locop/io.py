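"""Readers and writers for the plain-text interchange formats.

Expression travels as TSV (first column gene_id, header = sample ids); the
gene catalog as BED6 (start = TSS, end = TSS + 1, score encodes the biotype)
or minimal GTF; annotation tracks as BED6 with the strand column carrying
motif orientation and the name column the motif/label id.  All BED
coordinates are 0-based half-open; GTF is converted on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_catalog_bed",
    "write_catalog_bed",
    "read_catalog_gtf",
    "write_catalog_gtf",
    "read_bed_track",
    "write_bed_track",
]

_BIOTYPE_CODE = {"protein_coding": 1, "lincRNA": 2}
_CODE_BIOTYPE = {v: k for k, v in _BIOTYPE_CODE.items()}


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_expression(path: str | Path, state: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix.from_frame(df, state=state)


def write_catalog_bed(catalog: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": catalog["chrom"],
            "start": catalog["tss"],
            "end": catalog["tss"] + 1,
            "name": catalog["gene_id"],
            "score": catalog["biotype"].map(_BIOTYPE_CODE).fillna(0).astype(int),
            "strand": catalog["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_catalog_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "tss": bed["start"].astype(int),
            "strand": bed["strand"],
            "biotype": bed["score"].map(_CODE_BIOTYPE).fillna("other"),
        }
    )


def write_catalog_gtf(catalog: pd.DataFrame, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in catalog.itertuples(index=False):
            start = int(rec.tss) + 1  # GTF is 1-based inclusive
            attrs = f'gene_id "{rec.gene_id}"; gene_biotype "{rec.biotype}";'
            fh.write(
                f"{rec.chrom}\tlocop\tgene\t{start}\t{start}\t.\t{rec.strand}\t.\t{attrs}\n"
            )


def read_catalog_gtf(path: str | Path) -> pd.DataFrame:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                item.strip().split(" ", 1)
                for item in fields[8].strip().rstrip(";").split(";")
                if item.strip()
            )
            gene_id = attrs.get("gene_id", "").strip('"')
            biotype = attrs.get("gene_biotype", '"other"').strip('"')
            strand = fields[6]
            start1, end1 = int(fields[3]), int(fields[4])
            tss = start1 - 1 if strand != "-" else end1 - 1  # strand-aware, 0-based
            rows.append((gene_id, fields[0], tss, strand, biotype))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "biotype"])


def write_bed_track(track: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": track["chrom"],
            "start": track["start"],
            "end": track["end"],
            "name": track["label"],
            "score": 0,
            "strand": track["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed_track(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"].fillna("+"),
            "label": bed["name"],
        }
    )
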