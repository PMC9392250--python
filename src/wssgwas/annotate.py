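"""Gene annotation of significant regions and overlap with DE results.

Coordinates are 1-based inclusive throughout (GFF3 convention); BED input
is converted on read. A gene is assigned to a region when their closed
intervals overlap by at least one base. The differential-expression overlap
is a case-insensitive exact match on gene name against DEG rows passing the
FDR and fold-change thresholds; the sign of the log2 ratio is the caller's
orientation contract and is passed through verbatim.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "read_gff3",
    "read_bed",
    "read_deg_table",
    "genes_in_regions",
    "overlap_with_deg",
]

GENE_COLUMNS = ["gene_id", "gene_name", "chrom", "start_bp", "end_bp", "strand"]


def _chrom_to_int(values) -> np.ndarray:
    out = []
    for v in values:
        s = str(v)
        if s.lower().startswith("chr"):
            s = s[3:]
        out.append(int(s))
    return np.asarray(out, dtype=np.int64)


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene table from a GFF3 file (via an in-memory gffutils database)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(feature_type):
        name = (
            feat.attributes.get("Name")
            or feat.attributes.get("gene_name")
            or feat.attributes.get("ID")
            or [feat.id]
        )[0]
        rows.append(
            {
                "gene_id": feat.id,
                "gene_name": name,
                "chrom": feat.seqid,
                "start_bp": feat.start,
                "end_bp": feat.end,
                "strand": feat.strand,
            }
        )
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    genes["chrom"] = _chrom_to_int(genes["chrom"])
    return genes


def read_bed(path) -> pd.DataFrame:
    """Gene table from BED (0-based half-open converted to 1-based inclusive)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = pd.DataFrame(
        {
            "gene_id": bed[3] if bed.shape[1] > 3 else [f"feature{i}" for i in range(len(bed))],
            "gene_name": bed[3] if bed.shape[1] > 3 else [f"feature{i}" for i in range(len(bed))],
            "chrom": _chrom_to_int(bed[0]),
            "start_bp": bed[1].astype(np.int64) + 1,
            "end_bp": bed[2].astype(np.int64),
            "strand": bed[5] if bed.shape[1] > 5 else ".",
        }
    )
    return genes[GENE_COLUMNS]


def read_deg_table(
    path,
    gene_col: str = "gene",
    log2_col: str = "log2_ratio",
    fdr_col: str = "fdr",
) -> pd.DataFrame:
    deg = pd.read_csv(path, sep="\t")
    deg = deg.rename(columns={gene_col: "gene_name", log2_col: "log2_ratio", fdr_col: "fdr"})
    missing = {"gene_name", "log2_ratio", "fdr"} - set(deg.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    if ((deg["fdr"] < 0) | (deg["fdr"] > 1)).any():
        raise ValueError("FDR values outside [0, 1]")
    return deg


def genes_in_regions(regions: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign genes to regions by closed-interval overlap (>= 1 bp).

    ``regions`` needs chrom/start_bp/end_bp; genes may land in several
    regions. Unknown region chromosomes raise with the offenders listed.
    """
    for col in ("chrom", "start_bp", "end_bp"):
        if col not in regions.columns:
            raise ValueError(f"regions missing column {col!r}")
    ann_chroms = set(annotation["chrom"].tolist())
    unknown = sorted(set(regions["chrom"].tolist()) - ann_chroms)
    if unknown:
        raise ValueError(f"region chromosomes absent from annotation: {unknown}")
    out = []
    for ri, r in regions.reset_index(drop=True).iterrows():
        g = annotation[annotation["chrom"] == r["chrom"]]
        hit = g[(g["start_bp"] <= r["end_bp"]) & (g["end_bp"] >= r["start_bp"])]
        for _, row in hit.iterrows():
            out.append(
                {
                    "region": ri,
                    "chrom": int(r["chrom"]),
                    "region_start_bp": int(r["start_bp"]),
                    "region_end_bp": int(r["end_bp"]),
                    "gene_id": row["gene_id"],
                    "gene_name": row["gene_name"],
                    "gene_start_bp": int(row["start_bp"]),
                    "gene_end_bp": int(row["end_bp"]),
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "region", "chrom", "region_start_bp", "region_end_bp",
            "gene_id", "gene_name", "gene_start_bp", "gene_end_bp",
        ],
    )


def overlap_with_deg(
    region_genes: pd.DataFrame,
    deg: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_abs_log2fc: float = 1.0,
    trait: str | None = None,
) -> pd.DataFrame:
    """Intersect region genes with DEG rows passing the thresholds.

    Matching is a case-insensitive exact gene-name comparison; the output
    mirrors a trait / gene / log2 ratio / FDR / direction table. Thresholds
    default to FDR < 0.05 and |log2FC| >= 1 (fold change >= 2).
    """
    cols = ["trait", "gene_name", "log2_ratio", "fdr", "direction"]
    if deg.empty:
        warnings.warn("empty DEG table; overlap is empty", stacklevel=2)
        return pd.DataFrame(columns=cols)
    passing = deg[
        (deg["fdr"] < fdr_threshold) & (deg["log2_ratio"].abs() >= min_abs_log2fc)
    ]
    names = set(region_genes["gene_name"].astype(str).str.lower())
    hit = passing[passing["gene_name"].astype(str).str.lower().isin(names)]
    out = pd.DataFrame(
        {
            "trait": trait if trait is not None else "",
            "gene_name": hit["gene_name"].to_numpy(),
            "log2_ratio": hit["log2_ratio"].to_numpy(),
            "fdr": hit["fdr"].to_numpy(),
            "direction": np.where(hit["log2_ratio"].to_numpy() >= 0, "up", "down"),
        },
        columns=cols,
    )
    return out.reset_index(drop=True)
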