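"""Among-sample divergence: pairwise FST/Nm, hierarchical AMOVA, Mantel test.

FST between groups defaults to the Hudson/Slatkin estimator
``1 - Hw/Hb`` where Hw is the mean within-group pairwise difference
(averaged over the two groups) and Hb the mean between-group pairwise
difference. Gene flow for a haploid, maternally inherited marker follows
the island-model identity FST = 1/(1 + 2Nm), i.e. Nm = (1-FST)/(2 FST).

AMOVA is the Excoffier-Smouse-Quattro nested analysis of molecular
variance on squared distances (here the squared Euclidean convention for
haplotypic data: the raw nucleotide-difference count). Variance components
are solved from expected mean squares with unequal-sample-size
coefficients; Phi-statistics are tested by the standard three permutation
schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from .seqio import Alignment, DistanceMatrix, SampleMetadata, pairwise_differences

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FST / Nm
# ---------------------------------------------------------------------------

@dataclass
class PairwiseDivergence:
    labels: list[str]
    fst: np.ndarray
    nm: np.ndarray
    p: np.ndarray
    n_permutations: int
    estimator: str = "hudson"

    def to_frame(self) -> pd.DataFrame:
        """Square layout with FST below the diagonal and Nm above."""
        k = len(self.labels)
        out = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if i > j:
                    out[i, j] = self.fst[i, j]
                elif i < j:
                    out[i, j] = self.nm[i, j]
        return pd.DataFrame(out, index=self.labels, columns=self.labels)


def nm_from_fst(fst: float) -> float:
    """Effective migrants per generation implied by a haploid FST.

    Nm = (1 - FST)/(2 FST); FST <= 0 maps to +inf (no detectable
    restriction of gene flow), FST > 1 is a domain error.
    """
    if fst > 1.0:
        raise ValueError(f"FST {fst} > 1")
    if fst <= 0.0:
        logger.warning("FST <= 0: Nm reported as +inf")
        return math.inf
    return (1.0 - fst) / (2.0 * fst)


def hudson_fst(d: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    """Hudson/Slatkin FST = 1 - Hw/Hb from a pairwise-difference matrix."""
    da = d[np.ix_(idx_a, idx_a)]
    db = d[np.ix_(idx_b, idx_b)]
    na, nb = len(idx_a), len(idx_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 sequences")
    hw_a = da.sum() / (na * (na - 1))
    hw_b = db.sum() / (nb * (nb - 1))
    hw = 0.5 * (hw_a + hw_b)
    hb = d[np.ix_(idx_a, idx_b)].mean()
    if hb == 0:
        return 0.0
    return float(1.0 - hw / hb)


def weir_cockerham_fst(
    hap_labels: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> float:
    """Weir-Cockerham theta for haploid data, haplotypes as alleles."""
    groups = [idx_a, idx_b]
    r = 2
    sizes = np.array([len(g) for g in groups], float)
    n_tot = sizes.sum()
    nc = (n_tot - (sizes**2).sum() / n_tot) / (r - 1)
    alleles = np.unique(hap_labels[np.concatenate(groups)])
    msp_sum = msg_sum = denom = 0.0
    for a in alleles:
        freqs = np.array([(hap_labels[g] == a).mean() for g in groups])
        pbar = (sizes * freqs).sum() / n_tot
        msp = (sizes * (freqs - pbar) ** 2).sum() / (r - 1)
        msg = (sizes * freqs * (1 - freqs)).sum() / (n_tot - r)
        msp_sum += msp
        msg_sum += msg
        denom += msp + (nc - 1) * msg
    if denom == 0:
        return 0.0
    return float((msp_sum - msg_sum) / denom)


def pairwise_fst(
    aln: Alignment,
    meta: SampleMetadata,
    level: str = "area",
    estimator: str = "hudson",
    n_perm: int = 1000,
    seed: int | None = 0,
) -> PairwiseDivergence:
    """All pairwise FST (with permutation p-values) and implied Nm.

    ``level`` selects the grouping column ("area" or "location").
    Negative FST estimates are reported as computed; they are clamped to 0
    only for the Nm conversion (yielding +inf).
    """
    if level not in ("area", "location"):
        raise ValueError("level must be 'area' or 'location'")
    meta = meta.aligned_to(aln)
    labels_col = meta.table[level].to_numpy()
    groups = list(dict.fromkeys(labels_col))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    d = pairwise_differences(aln).values
    hap_codes = pd.Series(aln.seqs).astype("category").cat.codes.to_numpy()
    rng = np.random.default_rng(seed)
    k = len(groups)
    fst = np.zeros((k, k))
    pvals = np.ones((k, k))

    def _stat(ia, ib):
        if estimator == "hudson":
            return hudson_fst(d, ia, ib)
        if estimator == "weir":
            return weir_cockerham_fst(hap_codes, ia, ib)
        raise ValueError(f"unknown estimator {estimator!r}")

    for i in range(k):
        for j in range(i + 1, k):
            ia = np.flatnonzero(labels_col == groups[i])
            ib = np.flatnonzero(labels_col == groups[j])
            obs = _stat(ia, ib)
            pool = np.concatenate([ia, ib])
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool)
                if _stat(perm[: len(ia)], perm[len(ia):]) >= obs:
                    hits += 1
            fst[i, j] = fst[j, i] = obs
            pvals[i, j] = pvals[j, i] = (hits + 1) / (n_perm + 1)
    nm = np.full((k, k), math.inf)
    np.fill_diagonal(nm, 0.0)
    pos = fst > 0
    nm[pos] = (1.0 - fst[pos]) / (2.0 * fst[pos])
    return PairwiseDivergence(groups, fst, nm, pvals, n_perm, estimator)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    design: str  # "two-level" | "three-level"
    sigma: dict[str, float]  # variance components by level
    pct: dict[str, float]
    phi: dict[str, float]
    p: dict[str, float]
    df: dict[str, int]
    ss: dict[str, float]
    n_permutations: int
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in self.sigma:
            rows.append(
                {
                    "source": level,
                    "df": self.df[level],
                    "SS": self.ss[level],
                    "sigma2": self.sigma[level],
                    "pct_variance": self.pct[level],
                }
            )
        out = pd.DataFrame(rows)
        phi_rows = pd.DataFrame(
            [
                {"statistic": k, "value": v, "p": self.p.get(k, np.nan)}
                for k, v in self.phi.items()
            ]
        )
        out = out.merge(phi_rows, how="left", left_index=True, right_index=True)
        return out


def _half_within_sums(d2: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """For each group g: sum_{i<j in g} d2_ij, via one-hot matmul."""
    z = np.zeros((len(labels), k))
    z[np.arange(len(labels)), labels] = 1.0
    w = z.T @ d2 @ z
    return np.diag(w) / 2.0


def _components(
    d2: np.ndarray,
    pop_idx: np.ndarray,
    group_of_pop: np.ndarray | None,
):
    """Variance components of the nested analysis on squared distances.

    Returns (sigma_a, sigma_b, sigma_c, ss, df); for a two-level design
    (group_of_pop None) sigma_a is 0 and the 'among-group' entries absent.
    """
    n_tot = len(pop_idx)
    pops, pop_counts = np.unique(pop_idx, return_counts=True)
    p_n = len(pops)
    ss_total = d2.sum() / 2.0 / n_tot
    within_pop = _half_within_sums(d2, pop_idx, p_n)
    ssd_wp = float((within_pop / pop_counts).sum())

    if group_of_pop is None:
        df_ap, df_wp = p_n - 1, n_tot - p_n
        ssd_ap = ss_total - ssd_wp
        ms_wp = ssd_wp / df_wp if df_wp else np.nan
        n_coef = (n_tot - (pop_counts**2).sum() / n_tot) / df_ap
        sigma_c = ms_wp
        sigma_b = (ssd_ap / df_ap - sigma_c) / n_coef
        ss = {"among_locations": ssd_ap, "within_locations": ssd_wp}
        df = {"among_locations": df_ap, "within_locations": df_wp}
        return 0.0, sigma_b, sigma_c, ss, df

    groups = np.unique(group_of_pop)
    g_n = len(groups)
    grp_of_ind = group_of_pop[pop_idx]
    grp_sizes = np.array(
        [(grp_of_ind == g).sum() for g in groups], float
    )
    within_grp = _half_within_sums(
        d2, np.searchsorted(groups, grp_of_ind), g_n
    )
    ssd_wg = float((within_grp / grp_sizes).sum())
    ssd_wp_ = ssd_wp
    ssd_ap = ssd_wg - ssd_wp_
    ssd_ag = ss_total - ssd_wg
    df_ag, df_ap, df_wp = g_n - 1, p_n - g_n, n_tot - p_n

    # unequal-sample-size coefficients of the expected mean squares
    sum_np2_over_ng = 0.0
    for gi, g in enumerate(groups):
        members = pop_counts[group_of_pop[pops] == g]
        sum_np2_over_ng += (members**2).sum() / grp_sizes[gi]
    sum_np2_over_n = (pop_counts**2).sum() / n_tot
    sum_ng2_over_n = (grp_sizes**2).sum() / n_tot
    n_coef = (n_tot - sum_np2_over_ng) / df_ap if df_ap else np.nan
    n1_coef = (sum_np2_over_ng - sum_np2_over_n) / df_ag
    n2_coef = (n_tot - sum_ng2_over_n) / df_ag

    sigma_c = ssd_wp_ / df_wp if df_wp else np.nan
    sigma_b = (ssd_ap / df_ap - sigma_c) / n_coef if df_ap else 0.0
    sigma_a = (ssd_ag / df_ag - sigma_c - n1_coef * sigma_b) / n2_coef
    ss = {
        "among_areas": ssd_ag,
        "among_locations_within_areas": ssd_ap,
        "within_locations": ssd_wp_,
    }
    df = {
        "among_areas": df_ag,
        "among_locations_within_areas": df_ap,
        "within_locations": df_wp,
    }
    return sigma_a, sigma_b, sigma_c, ss, df


def amova(
    aln: Alignment,
    meta: SampleMetadata,
    design: str = "three-level",
    n_perm: int = 10000,
    seed: int | None = 0,
    d2: np.ndarray | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA on pairwise nucleotide differences.

    design:
      - "two-level": among locations / within locations (Phi_ST only).
      - "three-level": among areas / among locations within areas / within
        locations (Phi_CT, Phi_SC, Phi_ST).

    Permutation schemes follow the standard convention: Phi_ST permutes
    individuals among locations across the whole data set, Phi_SC permutes
    individuals among locations within their area, Phi_CT permutes whole
    locations among areas. p = (hits + 1)/(n_perm + 1).
    """
    if design not in ("two-level", "three-level"):
        raise ValueError("design must be 'two-level' or 'three-level'")
    meta = meta.aligned_to(aln)
    if d2 is None:
        d2 = pairwise_differences(aln).values
    locs = meta.locations
    loc_lookup = {l: i for i, l in enumerate(locs)}
    pop_idx = np.array([loc_lookup[l] for l in meta.table["location"]])
    notes: list[str] = []

    if design == "three-level":
        areas = meta.areas
        area_lookup = {a: i for i, a in enumerate(areas)}
        area_of_loc = meta.area_of_location()
        group_of_pop = np.array([area_lookup[area_of_loc[l]] for l in locs])
        if len(areas) < 2:
            raise ValueError("three-level design needs >= 2 areas")
        pops_per_area = np.bincount(group_of_pop)
        if (pops_per_area < 2).any():
            notes.append(
                "degenerate design: some area has a single location; "
                "Phi_SC estimated from the remaining areas' contrasts"
            )
    else:
        group_of_pop = None

    sa, sb, sc, ss, df = _components(d2, pop_idx, group_of_pop)
    total = sa + sb + sc
    degenerate = not np.isfinite(total) or total <= 0
    rng = np.random.default_rng(seed)

    if design == "two-level":
        sigma = {"among_locations": sb, "within_locations": sc}
        if degenerate:
            phi = {"Phi_ST": np.nan}
            pvals = {"Phi_ST": np.nan}
            pct = {k: np.nan for k in sigma}
            notes.append("zero total variance: Phi undefined")
        else:
            pct = {k: 100.0 * v / total for k, v in sigma.items()}
            phi_st = sb / total
            hits = 0
            for _ in range(n_perm):
                _, pb, pc, _, _ = _components(d2, rng.permutation(pop_idx), None)
                t = pb + pc
                if t > 0 and pb / t >= phi_st:
                    hits += 1
            phi = {"Phi_ST": phi_st}
            pvals = {"Phi_ST": (hits + 1) / (n_perm + 1)}
        return AmovaResult(
            design, sigma, pct, phi, pvals, df, ss, n_perm, degenerate, notes
        )

    sigma = {
        "among_areas": sa,
        "among_locations_within_areas": sb,
        "within_locations": sc,
    }
    if degenerate:
        phi = {k: np.nan for k in ("Phi_CT", "Phi_SC", "Phi_ST")}
        pvals = dict(phi)
        pct = {k: np.nan for k in sigma}
        notes.append("zero total variance: Phi undefined")
        return AmovaResult(
            design, sigma, pct, phi, pvals, df, ss, n_perm, degenerate, notes
        )
    pct = {k: 100.0 * v / total for k, v in sigma.items()}
    phi_ct = sa / total
    phi_sc = sb / (sb + sc) if (sb + sc) > 0 else np.nan
    phi_st = (sa + sb) / total
    hits = {"Phi_CT": 0, "Phi_SC": 0, "Phi_ST": 0}

    grp_of_ind = group_of_pop[pop_idx]
    within_area_indices = [
        np.flatnonzero(grp_of_ind == g) for g in range(len(meta.areas))
    ]
    for _ in range(n_perm):
        # Phi_ST: individuals among locations, whole data set
        perm = rng.permutation(pop_idx)
        pa, pb, pc, _, _ = _components(d2, perm, group_of_pop)
        t = pa + pb + pc
        if t > 0 and (pa + pb) / t >= phi_st:
            hits["Phi_ST"] += 1
        # Phi_SC: individuals among locations within their area
        perm = pop_idx.copy()
        for idx in within_area_indices:
            perm[idx] = perm[rng.permutation(idx)]
        pa, pb, pc, _, _ = _components(d2, perm, group_of_pop)
        if (pb + pc) > 0 and pb / (pb + pc) >= phi_sc:
            hits["Phi_SC"] += 1
        # Phi_CT: whole locations among areas
        gperm = rng.permutation(group_of_pop)
        pa, pb, pc, _, _ = _components(d2, pop_idx, gperm)
        t = pa + pb + pc
        if t > 0 and pa / t >= phi_ct:
            hits["Phi_CT"] += 1
    phi = {"Phi_CT": phi_ct, "Phi_SC": phi_sc, "Phi_ST": phi_st}
    pvals = {k: (h + 1) / (n_perm + 1) for k, h in hits.items()}
    return AmovaResult(
        design, sigma, pct, phi, pvals, df, ss, n_perm, degenerate, notes
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    z: float
    r: float
    p: float
    n_permutations: int
    method: str = "permutation"


def mantel_test(
    x: DistanceMatrix,
    y: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | None = 0,
    method: str = "permutation",
    alternative: str = "greater",
) -> MantelResult:
    """Mantel matrix-correspondence test.

    Z = sum over i<j of X_ij * Y_ij and r the Pearson correlation of the
    off-diagonal elements. p is obtained by randomly permuting the
    rows/columns of one matrix (``method="permutation"``), or exactly by
    enumerating all n! relabellings for n <= 7 (``method="exact"``).
    """
    if x.labels != y.labels:
        raise ValueError("distance matrices have different labels")
    n = x.n
    if n < 3:
        raise ValueError("Mantel test needs n >= 3")
    iu = np.triu_indices(n, 1)
    xv = x.values[iu]
    yv = y.values[iu]
    z_obs = float((xv * yv).sum())
    r_obs = float(np.corrcoef(xv, yv)[0, 1]) if xv.std() and yv.std() else np.nan

    def _z(perm):
        yp = y.values[np.ix_(perm, perm)][iu]
        return float((xv * yp).sum())

    def _beats(zp):
        if alternative == "greater":
            return zp >= z_obs
        if alternative == "less":
            return zp <= z_obs
        return abs(zp - np.mean(all_z)) >= abs(z_obs - np.mean(all_z))

    if method == "exact":
        if n > 7:
            raise ValueError("exact enumeration limited to n <= 7")
        all_z = [_z(np.array(p)) for p in iter_permutations(range(n))]
        hits = sum(1 for zp in all_z if _beats(zp))
        p = hits / len(all_z)
        return MantelResult(z_obs, r_obs, p, len(all_z), "exact")

    rng = np.random.default_rng(seed)
    all_z = []
    hits = 0
    for _ in range(n_perm):
        zp = _z(rng.permutation(n))
        if alternative in ("greater", "less"):
            hits += _beats(zp)
        else:
            all_z.append(zp)
    if alternative == "two-sided":
        mu = float(np.mean(all_z))
        hits = sum(abs(zp - mu) >= abs(z_obs - mu) for zp in all_z)
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(z_obs, r_obs, p, n_perm, "permutation")


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (fallback when nautical distances are
    not supplied; labelled as such in provenance)."""
    rad = np.radians
    phi1, phi2 = rad(lat1), rad(lat2)
    dphi = rad(lat2 - lat1)
    dlmb = rad(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2) ** 2
    return float(2 * 6371.0 * np.arcsin(np.sqrt(a)))


def geographic_distances(meta: SampleMetadata) -> DistanceMatrix:
    """Great-circle distances (km) between the metadata's locations."""
    locs = meta.locations
    coords = {}
    for loc in locs:
        row = meta.table[meta.table["location"] == loc].iloc[0]
        if not np.isfinite(row["lat"]) or not np.isfinite(row["lon"]):
            raise ValueError(f"location {loc!r} lacks coordinates")
        coords[loc] = (row["lat"], row["lon"])
    k = len(locs)
    v = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v[i, j] = v[j, i] = great_circle_km(*coords[locs[i]], *coords[locs[j]])
    return DistanceMatrix(locs, v)
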