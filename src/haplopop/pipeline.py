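"""End-to-end orchestration: one config in, a bundle of result tables out.

Given an alignment + metadata (real or synthetic), runs every stage of the
analysis — diversity table, two- and three-level AMOVA, pairwise FST/Nm,
Mantel isolation-by-distance, median-joining network, and per-area
demography — writing each artifact as TSV plus a provenance log recording
seeds, estimator choices and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .demography import demography_table
from .diversity import diversity_table, format_diversity_table
from .network import median_joining_network, subnetwork_separation
from .seqio import (
    Alignment,
    DistanceMatrix,
    SampleMetadata,
    collapse_haplotypes,
    read_alignment,
)
from .structure import amova, geographic_distances, mantel_test, pairwise_fst

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    metadata: str
    out_dir: str
    geo_distances: str | None = None  # TSV matrix; else great-circle fallback
    fst_estimator: str = "hudson"
    n_perm: int = 10000
    n_bootstrap: int = 1000
    n_sims: int = 1000
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every analysis stage; returns a dict of result objects.

    Output files (TSV + provenance.json) are written to cfg.out_dir.
    Partial outputs are retained if a later stage fails.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    aln, meta = read_alignment(cfg.fasta, cfg.metadata)
    results["n"] = aln.n

    def _fmt(x, nd):
        return np.round(x, nd)

    stage = "diversity"
    try:
        div = diversity_table(aln, meta)
        format_diversity_table(div).to_csv(out / "diversity.tsv", sep="\t", index=False)
        results["diversity"] = div
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "amova"
    try:
        multiple_areas = len(meta.areas) >= 2
        res2 = amova(aln, meta, "two-level", n_perm=cfg.n_perm, seed=cfg.seed)
        frames = {"two-level": res2}
        if multiple_areas:
            res3 = amova(aln, meta, "three-level", n_perm=cfg.n_perm, seed=cfg.seed)
            frames["three-level"] = res3
        else:
            logger.warning(
                "single area: three-level AMOVA degraded to two-level design"
            )
        for name, res in frames.items():
            df = res.to_frame()
            for col, nd in (("pct_variance", 2), ("value", 3)):
                if col in df:
                    df[col] = _fmt(df[col], nd)
            df.to_csv(out / f"amova_{name.replace('-', '_')}.tsv", sep="\t", index=False)
        results["amova"] = frames
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "fst"
    try:
        level = "area" if multiple_areas else "location"
        div_pair = pairwise_fst(
            aln, meta, level=level, estimator=cfg.fst_estimator,
            n_perm=min(cfg.n_perm, 1000), seed=cfg.seed,
        )
        div_pair.to_frame().round(3).to_csv(out / "fst_nm.tsv", sep="\t")
        results["fst"] = div_pair
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "mantel"
    geo_source = None
    try:
        locs_ok = meta.table[["lat", "lon"]].notna().all().all()
        if cfg.geo_distances:
            gd = pd.read_csv(cfg.geo_distances, sep="\t", index_col=0)
            geo = DistanceMatrix(list(gd.index), gd.to_numpy(float))
            geo_source = "user-supplied"
        elif locs_ok and len(meta.locations) >= 3:
            geo = geographic_distances(meta)
            geo_source = "great-circle fallback"
        else:
            geo = None
        if geo is not None:
            fst_loc = pairwise_fst(
                aln, meta, level="location", estimator=cfg.fst_estimator,
                n_perm=0, seed=cfg.seed,
            )
            fst_dm = DistanceMatrix(
                fst_loc.labels, np.clip(fst_loc.fst, 0, None)
            )
            order = [fst_dm.labels.index(l) for l in geo.labels]
            fst_dm = DistanceMatrix(
                geo.labels, fst_dm.values[np.ix_(order, order)]
            )
            results["mantel"] = mantel_test(
                fst_dm, geo, n_perm=cfg.n_perm, seed=cfg.seed
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "network"
    try:
        ht = collapse_haplotypes(aln, meta)
        net = median_joining_network(ht)
        net.edge_list().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        net.node_table().to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        results["haplotypes"] = ht
        results["network"] = net
        if multiple_areas:
            area_of_loc = meta.area_of_location()
            partition = {}
            for hap_id in ht.hap_ids:
                row = ht.counts.loc[hap_id]
                locs = row[row > 0].index
                partition[hap_id] = area_of_loc[locs[0]]
            results["separation"] = subnetwork_separation(net, partition)
            results["separation"].to_csv(
                out / "network_separation.tsv", sep="\t", index=False
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "demography"
    try:
        demo, curves = demography_table(
            aln, meta, n_bootstrap=cfg.n_bootstrap, n_sims=cfg.n_sims,
            seed=cfg.seed,
        )
        demo.round(4).to_csv(out / "demography.tsv", sep="\t", index=False)
        curves.round(6).to_csv(out / "mismatch_curves.tsv", sep="\t", index=False)
        results["demography"] = demo
        results["mismatch_curves"] = curves
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    provenance = {
        "package": "haplopop",
        "version": __version__,
        "seed": cfg.seed,
        "fst_estimator": cfg.fst_estimator,
        "n_permutations": cfg.n_perm,
        "n_bootstrap": cfg.n_bootstrap,
        "n_coalescent_sims": cfg.n_sims,
        "distance_handling": "pairwise deletion of gaps and Ns",
        "geographic_distances": geo_source,
        "inputs": {"fasta": str(cfg.fasta), "metadata": str(cfg.metadata)},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["provenance"] = provenance
    return results
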