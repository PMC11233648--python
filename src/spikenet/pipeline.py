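"""End-to-end orchestration: synthesize -> detect -> analyze -> report.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
a master seed; every stage seed is derived from the master seed, so a run is
reproducible table-for-table. One shared unit population receives a distinct
planted coupling set per stimulus label; per label the pipeline builds the
functional network, scores signed motifs against the surrogate ensemble,
partitions the network with the signed Louvain method, quantifies
module-area agreement, and scores recovery of the planted ground truth.
Motif-overlap tables compare constituent-neuron identity across labels.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, io, motifs, netmetrics, nulls, synth
from .ccg import DetectionParams, build_network, filter_units_by_rate
from .data import SpikeTrainSet, write_session
from .partition_metrics import adjusted_rand_index, contingency_table, coverage_purity

__all__ = ["RunConfig", "run_pipeline"]

SCHEMA_VERSION = "1"


@dataclass
class RunConfig:
    population: synth.PopulationConfig = field(default_factory=synth.PopulationConfig)
    stimuli: dict = field(
        default_factory=lambda: {"stim": synth.CouplingConfig()}
    )
    n_trials: int = 60
    n_bins: int = 1000
    bin_ms: float = 1.0
    modulation: synth.ModulationConfig | None = field(
        default_factory=synth.ModulationConfig
    )
    detection: DetectionParams = field(default_factory=DetectionParams)
    surrogates: nulls.SurrogateSpec = field(default_factory=nulls.SurrogateSpec)
    modularity: community.ModularityParams = field(
        default_factory=community.ModularityParams
    )
    louvain_runs: int = 200
    gamma_plus_grid: list | None = None
    gamma_minus_grid: list | None = None
    sweep_ensemble: int = 20
    pair_ensemble: int = 200
    seed: int = 0
    outdir: str = "results/run"

    @classmethod
    def demo(cls, outdir: str = "results/demo", seed: int = 0) -> "RunConfig":
        """Two stimulus types, 3 areas x 20 units, distinct coupling sets."""
        cfg = synth.CouplingConfig(
            n_couplings=12,
            frac_positive=1.0,
            lag_range=(2, 6),
            duration_range=(1, 3),
            transmission=0.5,
            n_pffl_triangles=4,
        )
        return cls(
            population=synth.PopulationConfig(
                areas={"V1": 20, "LM": 20, "AM": 20}, rate_hz=(15.0, 25.0)
            ),
            stimuli={"drifting_gratings": cfg, "natural_movie": cfg},
            gamma_plus_grid=[0.7, 1.0, 1.4],
            gamma_minus_grid=[1.0],
            # 25 calls x 8 internal restarts = 200 greedy descents per
            # protocol step, the study's optimization budget
            louvain_runs=25,
            seed=seed,
            outdir=outdir,
        )

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stimuli"] = {k: dataclasses.asdict(v) for k, v in self.stimuli.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x

        def build(klass, sub, tuples=()):
            sub = dict(sub or {})
            for key in tuples:
                if key in sub:
                    sub[key] = tup(sub[key])
            return klass(**sub)

        kwargs = dict(d)
        kwargs["population"] = build(
            synth.PopulationConfig, d.get("population"), ("rate_hz",)
        )
        kwargs["stimuli"] = {
            k: build(
                synth.CouplingConfig,
                v,
                ("lag_range", "duration_range", "transmission"),
            )
            for k, v in d.get("stimuli", {}).items()
        }
        mod = d.get("modulation")
        kwargs["modulation"] = build(synth.ModulationConfig, mod) if mod else None
        kwargs["detection"] = build(DetectionParams, d.get("detection"))
        kwargs["surrogates"] = build(nulls.SurrogateSpec, d.get("surrogates"))
        kwargs["modularity"] = build(
            community.ModularityParams, d.get("modularity")
        )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, **obj}, fh, indent=1,
                  default=default, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; write the artifact bundle under ``config.outdir``.

    Returns the in-memory artifacts (networks, tables, partitions,
    recovery reports, log). Identical config + seed gives identical tables;
    wall-clock timings live only in ``log.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log: dict = {"stages": {}, "seed": config.seed}
    t_start = time.perf_counter()

    def stage(name):
        log["stages"][name] = {"t": time.perf_counter() - t_start}
        return name

    # --- synthesize ----------------------------------------------------
    pop_seed = int(rng.integers(2**31 - 1))
    base_truth = synth.make_ground_truth(
        config.population,
        synth.CouplingConfig(n_couplings=0),
        config.modulation,
        seed=pop_seed,
    )
    truths: dict[str, synth.GroundTruthCouplings] = {}
    sessions = []
    for label in sorted(config.stimuli):
        truths[label] = synth.GroundTruthCouplings(
            couplings=synth.draw_couplings(
                base_truth.units, config.stimuli[label],
                int(rng.integers(2**31 - 1)),
            ),
            units=base_truth.units,
            modulation=config.modulation,
        )
        sessions.append(
            synth.simulate_session(
                truths[label],
                n_trials=config.n_trials,
                n_bins=config.n_bins,
                seed=int(rng.integers(2**31 - 1)),
                bin_ms=config.bin_ms,
                stimulus=label,
            )
        )
    data = SpikeTrainSet(
        spikes=np.concatenate([s.spikes for s in sessions]),
        trial_stimulus=np.concatenate([s.trial_stimulus for s in sessions]),
        units=sessions[0].units,
        bin_ms=config.bin_ms,
    )
    write_session(data, out / "session")
    for label, truth in truths.items():
        truth.couplings.to_csv(out / "session" / f"couplings_{label}.csv", index=False)
    stage("synthesize")

    # --- rate filter ---------------------------------------------------
    data = filter_units_by_rate(data, config.detection.min_rate_hz)
    log["n_units_kept"] = int(data.n_units)
    stage("rate_filter")

    catalog = motifs.motif_catalog(3, signed=True)
    areas = data.units["area"]
    networks: dict = {}
    results: dict = {
        "networks": networks, "summary": {}, "motif_z": {}, "pair_ratios": {},
        "partitions": {}, "partition_metrics": {}, "recovery": {},
    }
    pfflb_by_label: dict[str, dict] = {}

    for label in sorted(config.stimuli):
        ldir = out / label
        ldir.mkdir(exist_ok=True)
        net = build_network(data, config.detection, stimulus=label)
        networks[label] = net
        io.write_network(net, ldir)
        summary = netmetrics.summary_metrics(net)
        results["summary"][label] = summary
        _dump_json(
            {k: v for k, v in summary.items() if not isinstance(v, dict)},
            ldir / "summary.json",
        )
        stage(f"network[{label}]")

        recovery = synth.evaluate_recovery(truths[label], net)
        results["recovery"][label] = recovery
        _dump_json(recovery.as_dict(), ldir / "recovery.json")

        if net.number_of_edges() == 0:
            log["stages"][f"skipped[{label}]"] = "no edges detected"
            continue

        # motifs vs the default (signed-pair-preserving) reference
        spec = replace(config.surrogates, seed=int(rng.integers(2**31 - 1)))
        ensemble = nulls.surrogate_ensemble(net, spec)
        ztab = motifs.motif_zscores(net, ensemble, catalog)
        ztab.to_csv(ldir / "motif_zscores.csv")
        results["motif_z"][label] = ztab
        er_spec = nulls.SurrogateSpec(
            kind="erdos_renyi", n=config.pair_ensemble,
            seed=int(rng.integers(2**31 - 1)),
        )
        ptab = motifs.pair_relative_counts(
            net, nulls.surrogate_ensemble(net, er_spec)
        )
        ptab.to_csv(ldir / "pair_relative_counts.csv")
        results["pair_ratios"][label] = ptab
        pfflb_by_label[label] = motifs.pfflb_sets(net, catalog, area="V1")
        stage(f"motifs[{label}]")

        # modules at the best resolution on the sweep grid
        params = config.modularity
        if config.gamma_plus_grid:
            gp, gm, _ = community.resolution_sweep(
                net,
                config.gamma_plus_grid,
                config.gamma_minus_grid or [params.gamma_minus],
                spec=spec,
                params=params,
                n_runs=config.louvain_runs,
                ensemble_size=config.sweep_ensemble,
                seed=int(rng.integers(2**31 - 1)),
            )
            params = replace(params, gamma_plus=gp, gamma_minus=gm)
        seeds = rng.integers(0, 2**31 - 1, size=config.louvain_runs)
        runs = [community.louvain_signed(net, params, int(s)) for s in seeds]
        part = max(runs, key=lambda p: p.Q)
        zq = community.modularity_zscore(
            net, params, ensemble, seed=int(rng.integers(2**31 - 1))
        )
        part.labels.rename("module").to_csv(ldir / "partition.csv")
        results["partitions"][label] = part

        node_areas = areas.reindex(part.labels.index)
        if (part.labels != community.UNASSIGNED).sum() >= 2:
            cp = coverage_purity(part.labels, node_areas)
            ari = adjusted_rand_index(contingency_table(part.labels, node_areas))
            pm = {
                "gamma_plus": params.gamma_plus,
                "gamma_minus": params.gamma_minus,
                "Q": part.Q,
                **zq,
                "wa_coverage": cp.wa_coverage,
                "wa_purity": cp.wa_purity,
                "ari": ari,
                "n_modules": int(len(cp.per_module)),
            }
        else:
            pm = {"Q": part.Q, **zq, "note": "too few assigned nodes"}
        results["partition_metrics"][label] = pm
        _dump_json(pm, ldir / "partition_metrics.json")
        stage(f"modules[{label}]")

    # --- motif overlap across stimulus labels --------------------------
    if len(pfflb_by_label) >= 2:
        class_ids = sorted(
            {cid for sets in pfflb_by_label.values() for cid in sets}
        )
        frames = []
        for cid in class_ids:
            sets = {
                label: {
                    (cid, tuple(sorted(map(repr, t))))
                    for t in pfflb_by_label[label][cid].instances
                }
                for label in pfflb_by_label
            }
            tab = motifs.motif_overlap(sets)
            tab.insert(0, "motif", cid)
            frames.append(tab)
        overlap = pd.concat(frames, ignore_index=True)
        overlap["conditions"] = overlap["conditions"].map(
            lambda t: "+".join(t)
        )
        overlap.to_csv(out / "motif_overlap.csv", index=False)
        results["motif_overlap"] = overlap
    stage("overlap")

    config.to_yaml(out / "config.yaml")
    _dump_json(log, out / "log.json")
    _dump_json(
        {"files": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())},
        out / "manifest.json",
    )
    results["log"] = log
    return results
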