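"""Pooled CRISPRi screen processing: reads -> counts -> gene fitness.

The screen reads out gene fitness as the abundance change of guide-carrying
plasmids between a pre-induction (T0) and a post-induction (Tend) sample,
sequenced as exact 20-nt guide reads.  Counts are treated like RNA-seq
counts: median-of-ratios size factors, a per-guide negative-binomial
dispersion with a 1/mean trend, log2 fold changes with a delta-method
standard error, and a robust (median/MAD) gene-level aggregate.

No empirical-Bayes shrinkage of dispersions or fold changes is applied;
this is a documented simplification relative to full RNA-seq machinery.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GuideLibrary",
    "CountMatrix",
    "NormalizationModel",
    "count_guides",
    "estimate_size_factors",
    "estimate_dispersions",
    "guide_log2fc",
    "aggregate_gene_fitness",
]

GUIDE_LENGTH = 20
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_PRE_MEAN = 10.0

_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class GuideLibrary:
    """sgRNA library: unique guide ids, 20-nt sequences, target genes."""

    guide_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    genes: tuple[str, ...]

    def __post_init__(self):
        if len({*self.guide_ids}) != len(self.guide_ids):
            raise ValueError("guide ids must be unique")
        if len({*self.sequences}) != len(self.sequences):
            raise ValueError("library sequences must be unique")
        for seq in self.sequences:
            if len(seq) != GUIDE_LENGTH or not set(seq) <= _ALPHABET:
                raise ValueError(f"invalid guide sequence {seq!r}")

    def __len__(self) -> int:
        return len(self.guide_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GuideLibrary":
        return cls(
            tuple(df["guide_id"].astype(str)),
            tuple(df["sequence"].astype(str)),
            tuple(df["gene"].astype(str)),
        )


@dataclass
class CountMatrix:
    """Guides x samples integer count table with sample metadata.

    ``samples`` is a DataFrame with columns ``condition``, ``timepoint``
    ("pre"/"post") and ``replicate``; its index holds the sample names used
    as the column order of ``counts``.
    """

    guide_ids: list[str]
    genes: list[str]
    counts: np.ndarray
    samples: pd.DataFrame
    unmatched: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.guide_ids), len(self.samples)):
            raise ValueError("count matrix shape does not match guides x samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def sample_names(self) -> list[str]:
        return list(self.samples.index)

    def columns(self, condition: str, timepoint: str) -> np.ndarray:
        mask = (self.samples["condition"] == condition) & (
            self.samples["timepoint"] == timepoint
        )
        return np.flatnonzero(mask.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_names())
        df.insert(0, "gene", self.genes)
        df.insert(0, "guide_id", self.guide_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        """Read a count TSV with sample columns named condition_timepoint_rep."""
        df = pd.read_csv(path, sep="\t")
        sample_cols = [c for c in df.columns if c not in ("guide_id", "gene")]
        meta = []
        for col in sample_cols:
            parts = col.rsplit("_", 2)
            if len(parts) != 3 or parts[1] not in ("pre", "post"):
                raise ValueError(
                    f"sample column {col!r} is not named condition_timepoint_rep"
                )
            meta.append({"condition": parts[0], "timepoint": parts[1], "replicate": parts[2]})
        samples = pd.DataFrame(meta, index=sample_cols)
        return cls(
            guide_ids=list(df["guide_id"].astype(str)),
            genes=list(df["gene"].astype(str)),
            counts=df[sample_cols].to_numpy(dtype=np.int64),
            samples=samples,
        )


@dataclass
class NormalizationModel:
    """Size factors plus trended NB dispersions alpha(mu) = a0 + a1/mu."""

    size_factors: np.ndarray
    dispersions: np.ndarray
    trend_coefficients: tuple[float, float]


# ---------------------------------------------------------------------------
# FASTQ -> counts


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_sequences(handle):
    """Yield read sequences from a FASTQ stream (plain text handle)."""
    from Bio import SeqIO

    for record in SeqIO.parse(handle, "fastq"):
        yield str(record.seq)


def count_guides(reads, library: GuideLibrary) -> tuple[np.ndarray, int]:
    """Count exact guide matches in a stream of reads.

    A read is assigned to a guide iff its first 20 nt equal the guide
    sequence exactly; otherwise it increments the unmatched tally.  Reads
    shorter than 20 nt are unmatched.  ``reads`` may be a path to a FASTQ
    file (optionally gzipped) or an iterable of sequence strings.

    Returns ``(counts, unmatched)`` with ``counts.sum() + unmatched`` equal
    to the total number of reads.
    """
    lookup = {seq: i for i, seq in enumerate(library.sequences)}
    counts = np.zeros(len(library), dtype=np.int64)
    unmatched = 0
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        with _open_maybe_gzip(reads) as fh:
            return count_guides(iter_fastq_sequences(fh), library)
    for read in reads:
        idx = lookup.get(read[:GUIDE_LENGTH].upper()) if len(read) >= GUIDE_LENGTH else None
        if idx is None:
            unmatched += 1
        else:
            counts[idx] += 1
    return counts, unmatched


# ---------------------------------------------------------------------------
# Normalisation


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean one.

    Uses guides with non-zero counts in every sample as the reference set.
    """
    counts = np.asarray(counts, dtype=float)
    all_nonzero = np.all(counts > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError(
            "no guide has non-zero counts in all samples; supply a pseudo-"
            "reference or filter samples before normalisation"
        )
    ref = counts[all_nonzero]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Robust least squares for alpha(mu) = a0 + a1/mu on guides with alpha>0."""
    keep = (alpha > 0) & (mu > 0)
    if keep.sum() < 2:
        return (float(np.median(alpha[alpha > 0])) if np.any(alpha > 0) else 0.0, 0.0)
    x = 1.0 / mu[keep]
    y = alpha[keep]

    def resid(theta):
        return theta[0] + theta[1] * x - y

    sol = optimize.least_squares(
        resid, x0=[max(np.median(y), 1e-6), 1.0], loss="soft_l1",
        bounds=([0.0, 0.0], [np.inf, np.inf]),
    )
    return float(sol.x[0]), float(sol.x[1])


def estimate_dispersions(
    counts: np.ndarray, size_factors: np.ndarray, samples: pd.DataFrame
) -> NormalizationModel:
    """Trended NB dispersions from replicate variability.

    Per guide, a method-of-moments estimate on normalised counts pooled over
    replicate groups, ``alpha_i = max(0, (s^2 - mu) / mu^2)``, followed by a
    robust fit of the trend ``alpha(mu) = a0 + a1/mu``.  The trend value at
    each guide's mean is the final dispersion (no shrinkage).
    """
    counts = np.asarray(counts, dtype=float)
    groups = samples.groupby(["condition", "timepoint"], sort=True).indices
    if not groups or max(len(ix) for ix in groups.values()) < 2:
        raise ValueError("need at least two replicates in some (condition, timepoint)")
    norm = counts / np.asarray(size_factors)[None, :]

    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    mu_bar = np.zeros(counts.shape[0])
    weight = 0.0
    for ix in groups.values():
        ix = np.asarray(ix)
        if len(ix) < 2:
            continue
        grp = norm[:, ix]
        mu = grp.mean(axis=1)
        s2 = grp.var(axis=1, ddof=1)
        ok = mu > 0
        num[ok] += s2[ok] - mu[ok]
        den[ok] += mu[ok] ** 2
        mu_bar += mu * len(ix)
        weight += len(ix)
    mu_bar /= weight
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(den > 0, np.maximum(0.0, num / den), 0.0)

    a0, a1 = _fit_dispersion_trend(mu_bar, alpha_hat)
    with np.errstate(divide="ignore"):
        trend = np.where(mu_bar > 0, a0 + a1 / mu_bar, a0)
    dispersions = np.maximum(trend, 0.0)
    return NormalizationModel(
        size_factors=np.asarray(size_factors, dtype=float),
        dispersions=dispersions,
        trend_coefficients=(a0, a1),
    )


# ---------------------------------------------------------------------------
# Fold changes and gene aggregation


def guide_log2fc(
    cm: CountMatrix,
    model: NormalizationModel,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-guide log2 fold change post/pre induction with delta-method SE.

    Returns a DataFrame with columns guide_id, gene, mean_pre, mean_post,
    lfc, se and a ``usable`` flag (False when the guide is absent from all
    samples of the condition).
    """
    pre_ix = cm.columns(condition, "pre")
    post_ix = cm.columns(condition, "post")
    if len(pre_ix) == 0 or len(post_ix) == 0:
        raise ValueError(f"condition {condition!r} lacks pre or post samples")
    norm = cm.counts / model.size_factors[None, :]
    mean_pre = norm[:, pre_ix].mean(axis=1)
    mean_post = norm[:, post_ix].mean(axis=1)
    lfc = np.log2((mean_post + pseudocount) / (mean_pre + pseudocount))
    alpha = model.dispersions
    # NB variance mu + alpha mu^2; variance of a replicate-group mean; then
    # delta method through log2.
    var_pre = (mean_pre + alpha * mean_pre**2) / len(pre_ix)
    var_post = (mean_post + alpha * mean_post**2) / len(post_ix)
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_post / (mean_post + pseudocount) ** 2 + var_pre / (mean_pre + pseudocount) ** 2
    ) / ln2
    usable = (mean_pre + mean_post) > 0
    return pd.DataFrame(
        {
            "guide_id": cm.guide_ids,
            "gene": cm.genes,
            "condition": condition,
            "mean_pre": mean_pre,
            "mean_post": mean_post,
            "lfc": lfc,
            "se": se,
            "usable": usable,
        }
    )


def aggregate_gene_fitness(
    guide_lfc: pd.DataFrame, min_pre_mean: float = DEFAULT_MIN_PRE_MEAN
) -> pd.DataFrame:
    """Median/MAD aggregation of guide fold changes per gene.

    Guides flagged unusable or with pre-induction normalised mean below
    ``min_pre_mean`` (low coverage) are excluded.  Genes left with no usable
    guide are dropped with a warning.  The gene standard error is
    ``1.4826 * MAD / sqrt(n_guides)``.
    """
    import warnings

    keep = guide_lfc["usable"] & (guide_lfc["mean_pre"] >= min_pre_mean)
    dropped_genes = set(guide_lfc["gene"]) - set(guide_lfc.loc[keep, "gene"])
    if dropped_genes:
        warnings.warn(
            f"{len(dropped_genes)} gene(s) dropped with no usable guides",
            UserWarning,
            stacklevel=2,
        )
    rows = []
    for gene, grp in guide_lfc.loc[keep].groupby("gene", sort=True):
        vals = grp["lfc"].to_numpy()
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        rows.append(
            {
                "gene": gene,
                "condition": grp["condition"].iloc[0],
                "lfc": med,
                "se": 1.4826 * mad / np.sqrt(len(vals)),
                "n_guides": len(vals),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "condition", "lfc", "se", "n_guides"])
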