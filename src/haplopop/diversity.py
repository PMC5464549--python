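"""Within-sample diversity: haplotype diversity h and nucleotide diversity pi.

Both statistics follow Nei (1987). Haplotype (gene) diversity uses the
unbiased estimator h = n(1 - sum p_i^2)/(n - 1) with its sampling variance
(Nei 1987, eq. 8.12). Nucleotide diversity is the mean proportion of
differing sites over all unordered sequence pairs (pairwise deletion), which
equals the unbiased haplotype-frequency-weighted form; its default standard
deviation is the total (stochastic + sampling) variance for a
non-recombining locus (Nei 1987 eq. 10.7 / Tajima 1983), the convention the
classical mtDNA literature reports. A sequence-bootstrap, sampling-only
alternative is available via ``pi_sd_method="bootstrap"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Alignment, SampleMetadata, compared_sites, pairwise_differences

logger = logging.getLogger(__name__)


class InsufficientSampleError(ValueError):
    """Fewer sequences than the statistic requires (n >= 2)."""


@dataclass
class DiversityEstimates:
    """One row of a diversity table."""

    label: str
    n: int
    n_hap: int
    n_poly: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float


def haplotype_diversity(freqs) -> tuple[float, float]:
    """Unbiased haplotype diversity and its standard deviation.

    Parameters
    ----------
    freqs : sequence of positive int
        Haplotype counts; n = sum(freqs) must be >= 2.

    Returns
    -------
    (h, sd) with h = n(1 - sum p_i^2)/(n - 1) and sd the square root of
    Nei's (1987, eq. 8.12) sampling variance.
    """
    counts = np.asarray(list(freqs), float)
    if (counts <= 0).any() or counts.size == 0:
        raise ValueError("haplotype counts must be positive")
    n = counts.sum()
    if n < 2:
        raise InsufficientSampleError("haplotype diversity needs n >= 2")
    p = counts / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n * (1.0 - s2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2
    )
    return float(h), float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(
    aln: Alignment,
    pi_sd_method: str = "total",
    n_boot: int = 200,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its standard deviation.

    pi is the average over all n(n-1)/2 sequence pairs of (differences /
    sites compared), with pairwise deletion of gaps and Ns.

    pi_sd_method:
      - "total" (default): sqrt of Nei 1987 eq. 10.7, the no-recombination
        total (stochastic + sampling) variance.
      - "bootstrap": sampling-only, by resampling sequences with replacement.
    """
    n = aln.n
    if n < 2:
        raise InsufficientSampleError("nucleotide diversity needs n >= 2")
    pi = _pi_of(aln)
    if pi_sd_method == "total":
        L = aln.L
        var = (n + 1.0) / (3.0 * (n - 1.0)) * pi / L + (
            2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
        ) * pi**2
        sd = float(np.sqrt(max(var, 0.0)))
    elif pi_sd_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            boot = Alignment(
                [f"b{k}" for k in range(n)], [aln.seqs[i] for i in idx]
            )
            reps.append(_pi_of(boot))
        sd = float(np.std(reps, ddof=1))
    else:
        raise ValueError(f"unknown pi_sd_method {pi_sd_method!r}")
    return float(pi), sd


def _pi_of(aln: Alignment) -> float:
    d = pairwise_differences(aln).values
    m = compared_sites(aln).astype(float)
    iu = np.triu_indices(aln.n, 1)
    diffs, comp = d[iu], m[iu]
    ok = comp > 0
    if not ok.any():
        return 0.0
    return float(np.mean(diffs[ok] / comp[ok]))


def diversity_for(aln: Alignment, label: str = "", **kw) -> DiversityEstimates:
    ht_counts = pd.Series(aln.seqs).value_counts()
    h, h_sd = haplotype_diversity(ht_counts.to_numpy())
    pi, pi_sd = nucleotide_diversity(aln, **kw)
    return DiversityEstimates(
        label=label,
        n=aln.n,
        n_hap=int(len(ht_counts)),
        n_poly=aln.n_polymorphic(),
        h=h,
        h_sd=h_sd,
        pi=pi,
        pi_sd=pi_sd,
    )


def diversity_table(
    aln: Alignment, meta: SampleMetadata, **kw
) -> pd.DataFrame:
    """Per-location, pooled per-area, and total diversity estimates.

    Pooled rows are computed on the concatenated samples of their member
    locations (not by averaging the member estimates). Groups with fewer
    than two sequences are skipped with a warning.
    """
    meta = meta.aligned_to(aln)
    loc_series = meta.table["location"]
    area_series = meta.table["area"]
    rows: list[DiversityEstimates] = []

    def _try(indices, label, kind):
        if len(indices) < 2:
            logger.warning("skipping %s %r: fewer than 2 sequences", kind, label)
            return
        est = diversity_for(aln.subset(indices), label=label, **kw)
        rows.append((kind, est))

    for loc in meta.locations:
        _try(list(np.flatnonzero(loc_series == loc)), loc, "location")
    for area in meta.areas:
        _try(list(np.flatnonzero(area_series == area)), area, "area")
    _try(list(range(aln.n)), "TOTAL", "total")

    out = pd.DataFrame(
        [
            {
                "group": kind,
                "label": e.label,
                "N": e.n,
                "Nh": e.n_hap,
                "Np": e.n_poly,
                "h": e.h,
                "h_sd": e.h_sd,
                "pi": e.pi,
                "pi_sd": e.pi_sd,
            }
            for kind, e in rows
        ]
    )
    return out


def format_diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Round to reporting precision: h to 3 decimals, pi to 4."""
    out = table.copy()
    for c in ("h", "h_sd"):
        out[c] = out[c].round(3)
    for c in ("pi", "pi_sd"):
        out[c] = out[c].round(4)
    return out
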