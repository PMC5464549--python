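"""Structured-coalescent synthetic data emulating an mtDNA phylogeography survey.

The generator draws genealogies under a haploid n-island structured
coalescent: demes (sampling locations) grouped into biogeographical areas,
with scaled migration among demes within an area and among areas, an
optional sudden expansion (backwards in time, lineages coalesce faster
before the expansion), and an optional root-merge time at which all demes
collapse into a single small ancestral population. Time is measured in
units of N generations (per-deme haploid size); theta = 2*N*mu is the
scaled per-locus mutation rate, so a branch of length l carries
Poisson(theta/2 * l) mutations.

Sequences evolve under a finite-sites HKY model with a fixed invariant-site
mask (proportion ``p_inv``), the root drawn from the stationary base
frequencies; an infinite-sites mode (every mutation hits a fresh site) is
available for analytic cross-checks.

The shipped default configuration emulates a 13-location, 3-area survey of
312 individuals with high haplotype diversity, low nucleotide diversity,
star-like within-area genealogies and strong among-area divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .seqio import Alignment, SampleMetadata

TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T


@dataclass
class SimConfig:
    """Scenario for the structured-coalescent generator.

    areas: list of (area label, deme labels, per-deme sample sizes).
    theta: scaled mutation rate per locus (2*N*mu, current deme size).
    mig_within / mig_between: per-lineage scaled migration rates to demes
        of the same area / of other areas.
    expansion: (time, growth factor) — at ``time`` (backwards) every deme's
        size shrinks by ``factor``; None for constant size.
    merge_time: time at which all demes merge into one ancestral deme
        (required when mig_between == 0 with more than one area).
    """

    areas: list = field(default_factory=lambda: _DEFAULT_AREAS)
    theta: float = 10.0
    mig_within: float = 5.0
    mig_between: float = 0.0
    expansion: tuple | None = (0.3, 50.0)
    merge_time: float | None = 2.0
    seq_length: int = 537
    base_freqs: tuple = (0.227, 0.166, 0.187, 0.420)
    kappa: float = 5.0
    p_inv: float = 0.55
    infinite_sites: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for _, demes, sizes in self.areas:
            if len(demes) != len(sizes):
                raise ValueError("deme labels and sample sizes differ in length")
            if any(s < 1 for s in sizes):
                raise ValueError("sample sizes must be >= 1")
        for r in (self.theta, self.mig_within, self.mig_between):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if abs(sum(self.base_freqs) - 1.0) > 1e-6:
            raise ValueError("base_freqs must sum to 1")
        if self.expansion is not None:
            t, g = self.expansion
            if t < 0 or g <= 0:
                raise ValueError("expansion time >= 0 and factor > 0 required")

    @property
    def deme_labels(self) -> list[str]:
        return [d for _, demes, _ in self.areas for d in demes]

    @property
    def sample_sizes(self) -> list[int]:
        return [s for _, _, sizes in self.areas for s in sizes]

    @property
    def area_of_deme(self) -> list[int]:
        out = []
        for ai, (_, demes, _) in enumerate(self.areas):
            out += [ai] * len(demes)
        return out

    def to_text(self, path) -> None:
        lines = []
        for area, demes, sizes in self.areas:
            spec = ",".join(f"{d}:{s}" for d, s in zip(demes, sizes))
            lines.append(f"area.{area} = {spec}")
        for key in (
            "theta", "mig_within", "mig_between", "merge_time",
            "seq_length", "kappa", "p_inv", "infinite_sites", "seed",
        ):
            lines.append(f"{key} = {getattr(self, key)}")
        if self.expansion is not None:
            lines.append(f"expansion = {self.expansion[0]},{self.expansion[1]}")
        lines.append("base_freqs = " + ",".join(str(f) for f in self.base_freqs))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "SimConfig":
        areas, kw = [], {}
        for raw in open(path):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key.startswith("area."):
                demes, sizes = [], []
                for part in val.split(","):
                    d, _, s = part.partition(":")
                    demes.append(d.strip())
                    sizes.append(int(s))
                areas.append((key[5:], demes, sizes))
            elif key == "expansion":
                t, g = val.split(",")
                kw["expansion"] = (float(t), float(g))
            elif key == "base_freqs":
                kw["base_freqs"] = tuple(float(v) for v in val.split(","))
            elif key == "merge_time":
                kw["merge_time"] = None if val == "None" else float(val)
            elif key in ("seq_length", "seed"):
                kw[key] = int(val)
            elif key == "infinite_sites":
                kw[key] = val == "True"
            else:
                kw[key] = float(val)
        return cls(areas=areas, **kw)


# Default survey design: 13 locations in 3 areas, 312 individuals, with
# coordinates of a realistic NE-Atlantic / Mediterranean / Black-Sea transect.
_DEFAULT_AREAS = [
    ("NEA", ["SKE", "BIA", "TAN", "AGA"], [24, 24, 24, 25]),
    ("WCM", ["PRT", "BAI", "CSZ", "MLT", "GRA", "ZAT", "CAS"],
     [18, 24, 24, 24, 24, 24, 29]),
    ("ABS", ["VOL", "SOZ"], [24, 24]),
]

DEFAULT_COORDS = {
    "SKE": (58.521, -4.329), "BIA": (43.480, -1.570), "TAN": (35.794, -5.824),
    "AGA": (30.351, -9.591), "PRT": (37.581, -0.852), "BAI": (44.080, 9.890),
    "CSZ": (39.190, 9.570), "MLT": (35.900, 14.510), "GRA": (45.675, 13.386),
    "ZAT": (42.690, 18.040), "CAS": (40.030, 18.451), "VOL": (39.340, 22.940),
    "SOZ": (42.420, 27.700),
}


def default_config(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


@dataclass
class Genealogy:
    """Binary coalescent tree: tips 0..n-1, internal nodes in merge order."""

    n: int
    parent: np.ndarray  # length 2n-1, root has parent -1
    time: np.ndarray  # node times, coalescent units
    tip_deme: np.ndarray  # deme index per tip

    def __post_init__(self) -> None:
        assert len(self.parent) == 2 * self.n - 1

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(2 * self.n - 1)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                ch[par].append(node)
        return ch

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(2 * self.n - 1)
        ok = self.parent >= 0
        bl[ok] = self.time[self.parent[ok]] - self.time[np.flatnonzero(ok)]
        return bl


def simulate_genealogy(cfg: SimConfig, rng: np.random.Generator | None = None) -> Genealogy:
    """Draw one genealogy under the configured structured coalescent."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    area_of_deme = cfg.area_of_deme
    n_demes = len(area_of_deme)
    n_areas = len(cfg.areas)
    if cfg.mig_between == 0 and n_areas > 1 and cfg.merge_time is None:
        raise ValueError(
            "mig_between=0 with several areas makes the TMRCA infinite: "
            "set merge_time to give the demes a common ancestral population"
        )
    if cfg.mig_within == 0 and cfg.mig_between == 0 and n_demes > 1 \
            and cfg.merge_time is None:
        raise ValueError("isolated demes need a merge_time")

    sizes = cfg.sample_sizes
    n = sum(sizes)
    tip_deme = np.repeat(np.arange(n_demes), sizes)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    # active lineages per deme
    deme_of = {i: int(tip_deme[i]) for i in range(n)}
    by_deme: list[list[int]] = [[] for _ in range(n_demes)]
    for i in range(n):
        by_deme[tip_deme[i]].append(i)

    t = 0.0
    next_node = n
    t_exp, growth = (cfg.expansion if cfg.expansion is not None else (np.inf, 1.0))
    merge_time = cfg.merge_time if cfg.merge_time is not None else np.inf
    merged = False
    same_area = [
        [d for d in range(n_demes) if area_of_deme[d] == area_of_deme[e] and d != e]
        for e in range(n_demes)
    ]
    other_area = [
        [d for d in range(n_demes) if area_of_deme[d] != area_of_deme[e]]
        for e in range(n_demes)
    ]

    n_active = n
    while n_active > 1:
        fac = growth if t >= t_exp else 1.0
        coal_rates = np.array(
            [len(b) * (len(b) - 1) / 2.0 * fac for b in by_deme]
        )
        if merged:
            mig_rate = 0.0
        else:
            mig_rate = sum(
                len(by_deme[d])
                * ((cfg.mig_within if same_area[d] else 0.0)
                   + (cfg.mig_between if other_area[d] else 0.0))
                for d in range(n_demes)
            )
        total = coal_rates.sum() + mig_rate
        boundaries = [b for b in (t_exp, merge_time) if b > t and np.isfinite(b)]
        horizon = min(boundaries) if boundaries else np.inf
        if total <= 0:
            if not np.isfinite(horizon):
                raise RuntimeError("no events possible and no boundary ahead")
            t = horizon
        else:
            dt = rng.exponential(1.0 / total)
            if t + dt >= horizon:
                t = horizon
            else:
                t += dt
                u = rng.random() * total
                if u < coal_rates.sum():
                    d = int(np.searchsorted(np.cumsum(coal_rates), u))
                    pair = rng.choice(len(by_deme[d]), 2, replace=False)
                    i1, i2 = (by_deme[d][k] for k in sorted(pair, reverse=True))
                    for k in sorted(pair, reverse=True):
                        by_deme[d].pop(k)
                    node = next_node
                    next_node += 1
                    parent[i1] = parent[i2] = node
                    time[node] = t
                    by_deme[d].append(node)
                    deme_of[node] = d
                    n_active -= 1
                else:
                    # migration: pick lineage weighted by its deme's rate
                    weights = np.array(
                        [
                            len(by_deme[d])
                            * ((cfg.mig_within if same_area[d] else 0.0)
                               + (cfg.mig_between if other_area[d] else 0.0))
                            for d in range(n_demes)
                        ]
                    )
                    d = int(rng.choice(n_demes, p=weights / weights.sum()))
                    k = int(rng.integers(len(by_deme[d])))
                    lin = by_deme[d].pop(k)
                    rw = cfg.mig_within if same_area[d] else 0.0
                    rb = cfg.mig_between if other_area[d] else 0.0
                    if rng.random() * (rw + rb) < rw:
                        dest = int(rng.choice(same_area[d]))
                    else:
                        dest = int(rng.choice(other_area[d]))
                    by_deme[dest].append(lin)
                    deme_of[lin] = dest
                continue
        # hit a boundary
        if t == merge_time and not merged:
            merged = True
            alll = [lin for b in by_deme for lin in b]
            by_deme = [alll] + [[] for _ in range(n_demes - 1)]
        if t == t_exp:
            t_exp = -np.inf  # growth factor now permanently active

    return Genealogy(n=n, parent=parent, time=time, tip_deme=tip_deme)


def mutate_sequences(
    gen: Genealogy, cfg: SimConfig, rng: np.random.Generator | None = None,
    ids: list[str] | None = None,
) -> Alignment:
    """Scatter HKY mutations on a genealogy and emit tip sequences."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    if ids is None:
        ids = [f"t{i}" for i in range(gen.n)]
    if cfg.infinite_sites:
        return _mutate_infinite_sites(gen, cfg, rng, ids)
    L = cfg.seq_length
    freqs = np.asarray(cfg.base_freqs)
    variable = np.flatnonzero(rng.random(L) >= cfg.p_inv)
    root_seq = rng.choice(4, size=L, p=freqs)
    bl = gen.branch_lengths()
    seqs_codes = np.empty((2 * gen.n - 1, L), dtype=np.int8)
    order = np.argsort(-gen.time)  # root first
    seqs_codes[order[0]] = root_seq
    for node in order[1:]:
        par = gen.parent[node]
        seq = seqs_codes[par].copy()
        n_mut = rng.poisson(cfg.theta / 2.0 * bl[node])
        if n_mut and len(variable):
            sites = rng.choice(variable, size=n_mut)
            for s in sites:
                cur = seq[s]
                w = freqs.copy()
                w[cur] = 0.0
                ti = TRANSITION[int(cur)]
                w[ti] *= cfg.kappa
                seq[s] = rng.choice(4, p=w / w.sum())
        seqs_codes[node] = seq
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[seqs_codes[i]]) for i in range(gen.n)]
    return Alignment(list(ids), seqs)


def _mutate_infinite_sites(gen, cfg, rng, ids):
    bl = gen.branch_lengths()
    n_mut = rng.poisson(cfg.theta / 2.0 * bl)
    total = int(n_mut.sum())
    carrier = np.zeros((gen.n, total), dtype=np.uint8)
    tips_below = _tips_below(gen)
    col = 0
    for node in range(2 * gen.n - 1):
        for _ in range(n_mut[node]):
            carrier[tips_below[node], col] = 1
            col += 1
    bases = np.array(list("AT"))
    seqs = ["".join(bases[row]) for row in carrier]
    return Alignment(list(ids), seqs)


def _tips_below(gen: Genealogy) -> list[np.ndarray]:
    ch = gen.children()
    out: list[list[int]] = [[] for _ in range(2 * gen.n - 1)]
    for node in range(2 * gen.n - 1):  # children always have lower index
        if node < gen.n:
            out[node] = [node]
        else:
            out[node] = out[ch[node][0]] + out[ch[node][1]]
    return [np.array(v) for v in out]


def simulate_study(cfg: SimConfig) -> tuple[Alignment, SampleMetadata, dict]:
    """Full synthetic dataset: alignment, metadata, and a truth record."""
    rng = np.random.default_rng(cfg.seed)
    gen = simulate_genealogy(cfg, rng)
    labels = cfg.deme_labels
    ids = []
    rows = []
    area_label = {
        ai: area for ai, (area, _, _) in enumerate(cfg.areas)
    }
    area_of_deme = cfg.area_of_deme
    counter: dict[str, int] = {}
    for tip in range(gen.n):
        deme = int(gen.tip_deme[tip])
        loc = labels[deme]
        counter[loc] = counter.get(loc, 0) + 1
        sid = f"{loc}_{counter[loc]:03d}"
        ids.append(sid)
        lat, lon = DEFAULT_COORDS.get(loc, (np.nan, np.nan))
        rows.append(
            {"sample_id": sid, "location": loc,
             "area": area_label[area_of_deme[deme]], "lat": lat, "lon": lon}
        )
    aln = mutate_sequences(gen, cfg, rng, ids=ids)
    meta = SampleMetadata(pd.DataFrame(rows))
    truth = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "areas"},
        "n": gen.n,
        "tmrca": float(gen.time[gen.root]),
        "expansion": cfg.expansion,
        "mig_between": cfg.mig_between,
    }
    return aln, meta, truth


# ---------------------------------------------------------------------------
# Single-population helpers (null distributions, parametric bootstraps)
# ---------------------------------------------------------------------------

def single_population_genealogy(
    n: int, rng: np.random.Generator, expansion: tuple | None = None
) -> Genealogy:
    """Kingman coalescent for one deme, optionally with a sudden expansion
    (time, growth factor) at which, backwards, the rate multiplies."""
    t_exp, growth = expansion if expansion is not None else (np.inf, 1.0)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    node = n
    k = n
    while k > 1:
        rate = k * (k - 1) / 2.0 * (growth if t >= t_exp else 1.0)
        dt = rng.exponential(1.0 / rate)
        if t < t_exp <= t + dt:
            t = t_exp
            continue
        t += dt
        i, j = rng.choice(k, 2, replace=False)
        i, j = max(i, j), min(i, j)
        a, b = active.pop(i), active.pop(j)
        parent[a] = parent[b] = node
        time[node] = t
        active.append(node)
        node += 1
        k -= 1
    return Genealogy(n=n, parent=parent, time=time, tip_deme=np.zeros(n, np.int64))


def neutral_summary(n: int, theta: float, rng: np.random.Generator) -> tuple[int, float]:
    """(number of haplotypes, mean pairwise differences) for one neutral
    constant-size coalescent sample under the infinite-sites model."""
    gen = single_population_genealogy(n, rng)
    bl = gen.branch_lengths()
    muts = rng.poisson(theta / 2.0 * bl)
    ch = gen.children()
    # haplotype classes: tips separated by any mutated branch differ;
    # children always have a lower index than their parent, so a single
    # downward sweep suffices
    sig = np.zeros(2 * n - 1, dtype=np.int64)
    fresh = 1
    for node in range(2 * n - 3, -1, -1):
        par = gen.parent[node]
        if muts[node] > 0:
            sig[node] = fresh
            fresh += 1
        else:
            sig[node] = sig[par]
    k_hap = len(np.unique(sig[:n]))
    # pi from subtree sizes
    sizes = np.ones(2 * n - 1)
    for node in range(n, 2 * n - 1):
        sizes[node] = sum(sizes[c] for c in ch[node])
    c = sizes[:-1]  # root excluded (no branch above)
    m = muts[:-1]
    pi = float((m * 2.0 * c * (n - c)).sum() / (n * (n - 1.0)))
    return k_hap, pi


def expansion_mismatch_sample(
    n: int, tau: float, theta0: float, theta1: float,
    rng: np.random.Generator, max_classes: int | None = None,
) -> np.ndarray:
    """Pairwise-difference histogram of one coalescent sample under a
    sudden expansion (infinite sites).

    tau, theta0, theta1 are in the mismatch model's mutational units;
    internally the expansion time is tau/theta1 coalescent units and the
    growth factor theta1/theta0.
    """
    theta0 = max(theta0, 1e-6)
    growth = max(theta1 / theta0, 1.0)
    t_exp = tau / theta1 if theta1 > 0 else np.inf
    gen = single_population_genealogy(n, rng, expansion=(t_exp, growth))
    bl = gen.branch_lengths()
    muts = rng.poisson(theta1 / 2.0 * bl)
    # pairwise path mutation counts via post-order merge of tip lists
    ch = gen.children()
    hist: dict[int, int] = {}
    below: list[list[tuple[int, int]]] = [[] for _ in range(2 * n - 1)]
    for node in range(2 * n - 1):
        if node < n:
            below[node] = [(node, 0)]
        else:
            lists = []
            for c in ch[node]:
                lists.append([(tip, dist + muts[c]) for tip, dist in below[c]])
            a, b = lists
            for _, da in a:
                for _, db in b:
                    d = da + db
                    hist[d] = hist.get(d, 0) + 1
            below[node] = a + b
    d_max = max(hist) if hist else 0
    counts = np.zeros(d_max + 1, dtype=np.int64)
    for d, c in hist.items():
        counts[d] = c
    return counts
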