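"""Minimal expression-genetics stage for RIL populations.

Two pieces of machinery, matching what a cis-eQTL study needs at its core:

* a pairwise Pearson co-expression matrix (r, two-sided p, and an
  "ns" flag at a configurable alpha) over a lines x genes expression table;
* a single-marker least-squares LOD scan — Haley-Knott regression at the
  markers, no interval imputation — with a 1.5-LOD-drop support interval
  and a cis/trans call for the scanned gene.

Genotypes are coded 0/1 for the two homozygous parental classes of an
advanced RIL (no heterozygotes).  The scan statistic per marker is
LOD = (n/2) * log10(RSS0 / RSS1) = -(n/2) * log10(1 - r^2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class RilDataset:
    """Genotype/expression tables for a recombinant inbred line population.

    ``genotypes``: lines x markers DataFrame with values in {0, 1} (NaN for
    missing, at most 10% per marker); ``marker_positions``: per-marker
    (chromosome, cM, bp); ``expression``: lines x genes DataFrame;
    ``gene_positions``: per-gene (chromosome, bp).
    """

    genotypes: pd.DataFrame
    marker_positions: pd.DataFrame  # index: marker; columns: chrom, cM, bp
    expression: pd.DataFrame
    gene_positions: pd.DataFrame  # index: gene; columns: chrom, bp

    def __post_init__(self) -> None:
        g = self.genotypes.to_numpy(dtype=float)
        vals = g[~np.isnan(g)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("genotypes must be 0/1 (homozygous classes only)")
        miss = np.isnan(g).mean(axis=0)
        if (miss > 0.10).any():
            bad = self.genotypes.columns[int(np.argmax(miss))]
            raise ValueError(f"marker {bad!r} has >10% missing genotypes")
        if not self.genotypes.index.equals(self.expression.index):
            raise ValueError("genotype and expression line sets differ")
        if list(self.marker_positions.index) != list(self.genotypes.columns):
            raise ValueError("marker_positions do not match genotype columns")

    def write_tsv(self, out_dir: str | Path, prefix: str = "ril") -> None:
        out = Path(out_dir)
        self.genotypes.to_csv(out / f"{prefix}_genotypes.tsv", sep="\t")
        self.expression.to_csv(out / f"{prefix}_expression.tsv", sep="\t")
        self.marker_positions.to_csv(out / f"{prefix}_markers.tsv", sep="\t")
        self.gene_positions.to_csv(out / f"{prefix}_genes.tsv", sep="\t")

    @classmethod
    def read_tsv(cls, out_dir: str | Path, prefix: str = "ril") -> "RilDataset":
        out = Path(out_dir)
        return cls(
            genotypes=pd.read_csv(out / f"{prefix}_genotypes.tsv", sep="\t", index_col=0),
            marker_positions=pd.read_csv(out / f"{prefix}_markers.tsv", sep="\t", index_col=0),
            expression=pd.read_csv(out / f"{prefix}_expression.tsv", sep="\t", index_col=0),
            gene_positions=pd.read_csv(out / f"{prefix}_genes.tsv", sep="\t", index_col=0),
        )


def correlation_matrix(
    expression: pd.DataFrame, alpha: float = 0.05, min_obs: int = 3
) -> dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations over genes with two-sided p-values.

    Uses pairwise-complete observations; the p-value comes from the exact
    t transform with n-2 degrees of freedom.  Zero-variance genes yield NaN
    r/p for their pairs.  Returns {"r": ..., "p": ..., "ns": ...} DataFrames
    (ns = not significant at ``alpha``; NaN pairs are flagged ns).
    """
    genes = list(expression.columns)
    k = len(genes)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            x = expression.iloc[:, i].to_numpy(dtype=float)
            y = expression.iloc[:, j].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_obs:
                raise ValueError(
                    f"fewer than {min_obs} complete observations for "
                    f"({genes[i]}, {genes[j]})"
                )
            xi, yi = x[ok], y[ok]
            if xi.std() == 0 or yi.std() == 0:
                continue  # r undefined; stays NaN
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.pearsonr(xi, yi)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=genes, columns=genes)
    p_df = pd.DataFrame(p, index=genes, columns=genes)
    ns_df = pd.DataFrame(
        np.isnan(p) | (p >= alpha), index=genes, columns=genes
    )
    return {"r": r_df, "p": p_df, "ns": ns_df}


@dataclass
class LodProfile:
    """Marker-wise LOD scan result for one gene."""

    gene: str
    lod: pd.Series  # index: marker, values >= 0
    peak_marker: str
    support_interval: tuple[str, str]  # (left marker, right marker)
    classification: str | None = None  # "cis" | "trans" | None
    n_obs: pd.Series | None = None

    def to_frame(self, marker_positions: pd.DataFrame) -> pd.DataFrame:
        df = marker_positions.copy()
        df["LOD"] = self.lod
        return df.reset_index(names="marker")


def _marker_lod(geno: np.ndarray, expr: np.ndarray) -> tuple[float, int]:
    ok = ~(np.isnan(geno) | np.isnan(expr))
    g, y = geno[ok], expr[ok]
    n = len(g)
    if n < 3 or g.std() == 0 or y.std() == 0:
        return float("nan"), n
    r = float(np.corrcoef(g, y)[0, 1])
    r2 = min(r * r, 1.0 - 1e-15)
    return (n / 2.0) * -np.log10(1.0 - r2), n


def lod_scan(dataset: RilDataset, gene: str) -> LodProfile:
    """Single-marker regression LOD scan of one gene's expression.

    Per marker, LOD = (n/2) log10(RSS0/RSS1) for the least-squares
    regression of expression on the 0/1 genotype (RSS0 from the
    intercept-only model), computed via the equivalent -(n/2)log10(1-r^2).
    Monomorphic markers get LOD 0 with a warning.  The support interval is
    the contiguous run of markers around the peak (on the peak chromosome)
    whose LOD stays within 1.5 of the peak; the peak itself is the leftmost
    argmax.
    """
    if gene not in dataset.expression.columns:
        raise KeyError(gene)
    expr = dataset.expression[gene].to_numpy(dtype=float)
    markers = list(dataset.genotypes.columns)
    lods = np.zeros(len(markers))
    n_obs = np.zeros(len(markers), dtype=int)
    for k, m in enumerate(markers):
        lod, n = _marker_lod(dataset.genotypes[m].to_numpy(dtype=float), expr)
        if np.isnan(lod):
            logger.warning("marker %s monomorphic or degenerate: LOD set to 0", m)
            lod = 0.0
        lods[k] = lod
        n_obs[k] = n
    peak_idx = int(np.argmax(lods))  # argmax is leftmost on ties
    peak = markers[peak_idx]
    chrom = dataset.marker_positions.loc[peak, "chrom"]
    on_chrom = dataset.marker_positions["chrom"] == chrom
    threshold = lods[peak_idx] - 1.5
    left = peak_idx
    while left - 1 >= 0 and on_chrom.iloc[left - 1] and lods[left - 1] >= threshold:
        left -= 1
    right = peak_idx
    while (
        right + 1 < len(markers)
        and on_chrom.iloc[right + 1]
        and lods[right + 1] >= threshold
    ):
        right += 1
    return LodProfile(
        gene=gene,
        lod=pd.Series(lods, index=markers),
        peak_marker=peak,
        support_interval=(markers[left], markers[right]),
        n_obs=pd.Series(n_obs, index=markers),
    )


def classify_cis_trans(
    profile: LodProfile,
    gene_position: tuple[str, int],
    marker_positions: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> str:
    """Call an eQTL cis or trans relative to the scanned gene's position.

    Cis iff the gene lies on the peak marker's chromosome and either within
    ``window_bp`` of the peak marker or inside the 1.5-LOD support interval;
    trans otherwise.
    """
    gene_chrom, gene_bp = gene_position
    peak = marker_positions.loc[profile.peak_marker]
    if peak["chrom"] != gene_chrom:
        return "trans"
    if abs(int(peak["bp"]) - int(gene_bp)) <= window_bp:
        return "cis"
    left, right = profile.support_interval
    lo = int(marker_positions.loc[left, "bp"])
    hi = int(marker_positions.loc[right, "bp"])
    if marker_positions.loc[left, "chrom"] == gene_chrom and lo <= gene_bp <= hi:
        return "cis"
    return "trans"


def scan_and_classify(
    dataset: RilDataset, gene: str, window_bp: int = 1_000_000
) -> LodProfile:
    """Convenience: LOD scan plus cis/trans call from the dataset positions."""
    profile = lod_scan(dataset, gene)
    pos = dataset.gene_positions.loc[gene]
    profile.classification = classify_cis_trans(
        profile, (pos["chrom"], int(pos["bp"])), dataset.marker_positions, window_bp
    )
    return profile
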