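"""End-to-end pipeline orchestration.

Stages run in the fixed order: inputs -> network -> metrics -> screen ->
featurize -> train -> risk. Every stage writes its artifacts into the output
directory and registers them (with content hashes) in ``manifest.json``;
a stage failure halts the run with the stage name and persists the partial
manifest. A single global seed fans out to per-stage seeds by fixed offsets
so stages are independently reproducible.

Configuration lives in a YAML/JSON file mirroring :class:`PipelineConfig`;
inputs are either the four CSV tables (ports, trips, trade, environment) or
a synthetic world specification.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import linkscreen, metrics, network, risk, synthetic, training
from .features import assemble_samples, samples_to_jsonl, scale_features
from .models import DeepGravitySpec, TransformerGravitySpec
from .regions import encode_regions
from .training import TrainConfig, cross_validate, prediction_pairs

logger = logging.getLogger(__name__)

# Fixed per-stage seed offsets from the global seed.
SEED_OFFSETS = {"world": 0, "screen": 1, "model": 2, "folds": 3}

STAGES = ("inputs", "network", "metrics", "screen", "featurize", "train", "risk")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # Input tables; all four must be given, or none (synthetic world).
    registry_path: str | None = None
    trips_path: str | None = None
    trade_path: str | None = None
    env_path: str | None = None
    region_mapping_path: str | None = None
    synthetic: dict = field(default_factory=dict)   # WorldConfig overrides
    screen: dict = field(default_factory=dict)      # ScreenConfig overrides
    model: str = "transformer"                      # or "deepgravity"
    layers: int = 3
    train: dict = field(default_factory=dict)       # TrainConfig overrides
    weight_mode: str = "trips"
    pseudo_weight: float = network.DEFAULT_PSEUDO_WEIGHT
    bwra_bins: int = risk.DEFAULT_BINS

    def __post_init__(self) -> None:
        paths = [self.registry_path, self.trips_path, self.trade_path, self.env_path]
        given = [p is not None for p in paths]
        if any(given) and not all(given):
            raise ValueError("provide all four input tables or none (synthetic mode)")
        if self.model not in ("transformer", "deepgravity"):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def is_synthetic(self) -> bool:
        return self.registry_path is None

    def model_spec(self):
        if self.model == "transformer":
            return TransformerGravitySpec(encoder_layers=self.layers)
        return DeepGravitySpec(total_hidden_layers=self.layers)


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON pipeline configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, cfg: PipelineConfig, out: Path):
        self.out = out
        self.data = {
            "config": dataclasses.asdict(cfg),
            "seed": cfg.seed,
            "stage_seeds": {k: cfg.seed + v for k, v in SEED_OFFSETS.items()},
            "stages": {},
        }

    def record(self, stage: str, artifacts: list[Path], extra: dict | None = None) -> None:
        self.data["stages"][stage] = {
            "artifacts": {str(p.relative_to(self.out)): _sha256(p) for p in artifacts},
            **(extra or {}),
        }
        self.write()

    def write(self) -> None:
        (self.out / "manifest.json").write_text(json.dumps(self.data, indent=2))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg, out)
    state: dict = {}
    for stage in STAGES:
        try:
            _run_stage(stage, cfg, out, state, manifest)
        except Exception as exc:
            manifest.data["failed_stage"] = stage
            manifest.write()
            raise PipelineStageError(stage, exc) from exc
    return manifest.data


def _run_stage(stage: str, cfg: PipelineConfig, out: Path, state: dict, man: _Manifest) -> None:
    seed = man.data["stage_seeds"]
    if stage == "inputs":
        if cfg.is_synthetic:
            wc = synthetic.WorldConfig(**{**cfg.synthetic, "seed": seed["world"]})
            world = synthetic.generate(wc)
            state.update(
                registry=world.ports, trips=world.trips, trade=world.trade,
                env=world.env, region_mapping=world.region_mapping, world=world,
            )
        else:
            state.update(
                registry=network.load_registry(cfg.registry_path),
                trips=network.load_trips(cfg.trips_path),
                trade=pd.read_csv(cfg.trade_path),
                env=risk.load_env_table(cfg.env_path),
                region_mapping=(pd.read_csv(cfg.region_mapping_path)
                                if cfg.region_mapping_path else None),
                world=None,
            )
        network.save_registry(state["registry"], out / "ports.csv")
        state["trips"].to_csv(out / "trips.csv", index=False)
        state["trade"].to_csv(out / "trade.csv", index=False)
        risk.save_env_table(state["env"], out / "environment.csv")
        man.record(stage, [out / f for f in
                           ("ports.csv", "trips.csv", "trade.csv", "environment.csv")])
    elif stage == "network":
        net = network.build_network(state["trips"], state["registry"])
        weak, strong = network.components(net)
        state["net"] = net
        network.to_graphml(net, out / "network.graphml")
        man.record(stage, [out / "network.graphml"],
                   {"ports": net.n_ports(), "edges": net.n_edges(),
                    "weak_components": len(weak), "strong_components": len(strong)})
    elif stage == "metrics":
        table = metrics.node_metrics(state["net"], cfg.weight_mode)
        state["metrics"] = table
        table.to_csv(out / "node_metrics.csv")
        man.record(stage, [out / "node_metrics.csv"])
    elif stage == "screen":
        full = network.fully_connect(state["net"], cfg.pseudo_weight)
        provider = state["world"].route_provider if state.get("world") else None
        feats = linkscreen.build_edge_features(full, provider=provider)
        balanced = linkscreen.sample_pseudo_links(feats, seed=seed["screen"])
        sc = linkscreen.ScreenConfig(**{**cfg.screen, "seed": seed["screen"]})
        screen, report = linkscreen.train_link_classifier(balanced, sc)
        retained = linkscreen.screen_links(full, screen, feats)
        state["retained"] = retained
        pd.DataFrame(sorted(retained), columns=["source", "dest"]).to_csv(
            out / "retained_links.csv", index=False)
        report.to_csv(out / "screen_report.csv")
        man.record(stage, [out / "retained_links.csv", out / "screen_report.csv"],
                   {"filter_model": screen.name, "retained": len(retained)})
    elif stage == "featurize":
        table = encode_regions(state["registry"], state["region_mapping"])
        samples = assemble_samples(state["net"], state["metrics"], table,
                                   state["trade"], state["retained"])
        scaled, scaler = scale_features(samples)
        state.update(samples=samples, scaled=scaled, scaler=scaler, regions=table)
        samples_to_jsonl(samples, out / "samples.jsonl")
        man.record(stage, [out / "samples.jsonl"], {"n_samples": len(samples)})
    elif stage == "train":
        spec = cfg.model_spec()
        tc = TrainConfig(**{**cfg.train, "seed": seed["model"]})
        report = cross_validate(spec, state["scaled"], tc)
        model, _ = training.train(
            training.build_model(spec, seed["model"]), state["scaled"], tc)
        state["model"] = model
        (out / "evaluation.json").write_text(json.dumps(report.to_dict(), indent=2))
        preds = []
        for s in state["scaled"]:
            yhat = training.predict_sample(model, s)
            preds.extend(
                {"source": s.source, "region": r, "y_hat": float(h), "y": float(t)}
                for r, h, t in zip(s.regions, yhat, s.y)
            )
        with open(out / "predictions.jsonl", "w") as fh:
            for row in preds:
                fh.write(json.dumps(row) + "\n")
        man.record(stage, [out / "evaluation.json", out / "predictions.jsonl"],
                   report.to_dict())
    elif stage == "risk":
        observed = {
            (u, v): state["net"].weight(u, v) for u, v in state["net"].real_edges()
        }
        predicted = predicted_port_flows(state["model"], state["scaled"],
                                         state["net"], state["regions"])
        truth = risk.weight_distribution(observed, state["env"], bins=cfg.bwra_bins)
        bin_max = float(truth.bin_edges[-1])
        pred = risk.weight_distribution(predicted, state["env"], bins=cfg.bwra_bins,
                                        bin_max=bin_max)
        cmp = risk.compare_distributions(pred, truth)
        truth.pairs.to_csv(out / "risk_observed.csv", index=False)
        pred.pairs.to_csv(out / "risk_predicted.csv", index=False)
        (out / "risk_summary.json").write_text(json.dumps(cmp, indent=2))
        man.record(stage, [out / "risk_observed.csv", out / "risk_predicted.csv",
                           out / "risk_summary.json"], cmp)
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")


def predicted_port_flows(model, samples, net, regions) -> dict[tuple[str, str], float]:
    """Distribute predicted region flows over ports for risk weighting.

    A source's predicted flow into a region is split across the region's
    ports that the source actually connects to (else all member ports),
    proportionally to each port's total observed in-flux (uniformly when all
    are zero). Total predicted weight per source is conserved.
    """
    influx = {p: 0.0 for p in net.port_ids}
    for u, v in net.real_edges():
        influx[v] += net.weight(u, v)
    out: dict[tuple[str, str], float] = {}
    for s in samples:
        yhat = training.predict_sample(model, s)
        for r, flow in zip(s.regions, yhat):
            members = [p for p in regions.region_ports[r] if p in influx and p != s.source]
            if not members:
                continue
            linked = [p for p in members if net.graph.has_edge(s.source, p)]
            targets = linked or members
            w = np.array([influx[p] for p in targets])
            shares = w / w.sum() if w.sum() > 0 else np.full(len(targets), 1.0 / len(targets))
            for p, share in zip(targets, shares):
                out[(s.source, p)] = out.get((s.source, p), 0.0) + flow * share
    return out
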