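"""End-to-end pipeline: simulate/load -> reconstruct -> segment -> measure -> compare.

The pipeline is driven by a plain config (dict, JSON or YAML file) naming
one localization table or simulation block per condition plus all stage
parameters.  It writes per-condition TubuleRecord CSVs, the width and
intensity distribution summaries, the Kruskal-Wallis results and a JSON
provenance report (every parameter actually used, seeds, versions,
per-stage counts).  Any stage failure aborts with the stage name and
removes partial outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .morphometry import measure_field
from .reconstruction import read_localizations
from .segmentation import VesselnessParams
from .simulate import FieldSpec, straight_tubule, make_tubule_field
from .stats import kruskal_wallis, width_distribution

__all__ = [
    "PipelineError",
    "measure_simulated_tubules",
    "run_pipeline",
    "load_config",
]

_MAX_SEED = 2**31 - 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULTS = {
    "reconstruction": {"pixel_size": 20.0},
    "segmentation": {"sigmas": [1.0, 1.5, 2.0], "beta": 0.5, "c": None,
                     "threshold": "otsu"},
    "morphometry": {"measure_pixel_size": None, "straightness_min": 0.92,
                    "min_branch_px": 5},
    "stats": {"bin_width": 20.0, "max_width": 300.0},
}


def _merged(config: dict, section: str) -> dict:
    out = dict(DEFAULTS[section])
    out.update(config.get(section, {}))
    return out


def measure_simulated_tubules(
    diameters,
    *,
    tubule_length: float = 2000.0,
    labeling_density: float = 0.5,
    locs_per_emitter: float = 4.0,
    precision: float = 2.0,
    background_density: float = 0.0,
    seed: int = 0,
    orientations=None,
    recon_pixel_size: float = 5.0,
    seg_params: VesselnessParams | None = None,
    measure_pixel_size: float | None = None,
    threshold_method="otsu",
    straightness_min: float = 0.92,
    min_branch_px: int = 5,
    condition: str = "",
) -> pd.DataFrame:
    """Simulate one isolated straight tubule per diameter and measure each.

    Every tubule is placed in its own small field at a random orientation
    (or the given per-tubule ``orientations``), so each field yields one
    dominant straight branch; the longest measured branch per field is
    kept.  Per-field seeds derive from ``seed`` through the seeded RNG.
    Returns the concatenated TubuleRecord table with a ``true_diameter``
    column appended.
    """
    diameters = np.asarray(diameters, dtype=float)
    rng = np.random.default_rng(seed)
    seg_params = seg_params or VesselnessParams()
    margin = 200.0 + 2 * float(diameters.max())
    records = []
    for i, diam in enumerate(diameters):
        angle = (
            float(orientations[i]) if orientations is not None
            else float(rng.uniform(-math.pi / 2, math.pi / 2))
        )
        field_seed = int(rng.integers(0, _MAX_SEED))
        # field large enough to hold the tubule at any orientation
        size = tubule_length + 2 * margin
        cx = cy = size / 2
        start = (cx - tubule_length / 2 * math.cos(angle),
                 cy - tubule_length / 2 * math.sin(angle))
        spec = FieldSpec(
            field_size=(size, size),
            tubules=(straight_tubule(start, angle, tubule_length, diam, label=i),),
            labeling_density=labeling_density,
            locs_per_emitter_mean=locs_per_emitter,
            loc_precision_sigma=precision,
            background_density=background_density,
            seed=field_seed,
        )
        locs, _ = make_tubule_field(spec)
        if len(locs) == 0:
            continue
        df, _ = measure_field(
            locs,
            recon_pixel_size=recon_pixel_size,
            seg_params=seg_params,
            measure_pixel_size=measure_pixel_size,
            threshold_method=threshold_method,
            straightness_min=straightness_min,
            min_branch_px=min_branch_px,
            condition=condition,
        )
        if len(df) == 0:
            continue
        best = df.sort_values("length_nm", ascending=False).iloc[[0]].copy()
        best["true_diameter"] = diam
        best["tubule_index"] = i
        records.append(best)
    if not records:
        return pd.DataFrame()
    return pd.concat(records, ignore_index=True)


def _simulate_condition(sim_cfg: dict, seed: int, pipe_kwargs: dict,
                        condition: str) -> pd.DataFrame:
    """Draw a per-condition diameter mixture and measure every tubule."""
    n = int(sim_cfg.get("n_tubules", 100))
    p_bundle = float(sim_cfg.get("p_bundle", 0.0))
    single_d = float(sim_cfg.get("single_diameter", 25.0))
    b_lo, b_hi = sim_cfg.get("bundle_diameter", [50.0, 100.0])
    rng = np.random.default_rng(seed)
    is_bundle = rng.uniform(size=n) < p_bundle
    diameters = np.where(is_bundle, rng.uniform(b_lo, b_hi, size=n), single_d)
    sim_seed = int(rng.integers(0, _MAX_SEED))
    return measure_simulated_tubules(
        diameters,
        tubule_length=float(sim_cfg.get("tubule_length", 2000.0)),
        labeling_density=float(sim_cfg.get("labeling_density", 0.5)),
        locs_per_emitter=float(sim_cfg.get("locs_per_emitter", 4.0)),
        precision=float(sim_cfg.get("precision", 2.0)),
        background_density=float(sim_cfg.get("background_density", 0.0)),
        seed=sim_seed,
        condition=condition,
        **pipe_kwargs,
    )


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full analysis for every condition in ``config``.

    Each entry of ``config["conditions"]`` maps a condition name to either
    ``{"table": <csv path>}`` or ``{"simulate": {...}}``.  Outputs land in
    ``outdir``: ``records_<condition>.csv``, ``distributions.json``,
    ``stats.json`` and ``report.json``.  Returns the report dict.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    try:
        conditions = config.get("conditions")
        if not conditions:
            raise PipelineError("config", "no conditions defined")
        seed = int(config.get("seed", 0))
        recon = _merged(config, "reconstruction")
        seg = _merged(config, "segmentation")
        morpho = _merged(config, "morphometry")
        stats_cfg = _merged(config, "stats")
        seg_params = VesselnessParams(
            sigmas=tuple(seg["sigmas"]), beta=seg["beta"], c=seg["c"]
        )
        pipe_kwargs = dict(
            recon_pixel_size=float(recon["pixel_size"]),
            seg_params=seg_params,
            measure_pixel_size=morpho["measure_pixel_size"],
            threshold_method=seg["threshold"],
            straightness_min=float(morpho["straightness_min"]),
            min_branch_px=int(morpho["min_branch_px"]),
        )

        all_records: dict[str, pd.DataFrame] = {}
        counts: dict[str, dict] = {}
        for idx, (name, spec) in enumerate(sorted(conditions.items())):
            if "table" in spec:
                path = Path(spec["table"])
                if not path.exists():
                    raise PipelineError("input", f"missing input path: {path}")
                try:
                    locs = read_localizations(path)
                except Exception as exc:  # noqa: BLE001
                    raise PipelineError("input", f"{path}: {exc}") from exc
                df, meta = measure_field(locs, condition=name, **pipe_kwargs)
                counts[name] = meta
            elif "simulate" in spec:
                cond_seed = (seed * 1009 + idx * 7919) % _MAX_SEED
                df = _simulate_condition(spec["simulate"], cond_seed,
                                         pipe_kwargs, name)
                counts[name] = {"n_measured": int(len(df)), "seed": cond_seed}
            else:
                raise PipelineError(
                    "config", f"condition {name!r} needs a 'table' or 'simulate' block"
                )
            if len(df) == 0:
                raise PipelineError("morphometry", f"no tubules measured for {name!r}")
            all_records[name] = df
            p = outdir / f"records_{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)

        bin_width = float(stats_cfg["bin_width"])
        max_width = float(stats_cfg["max_width"])
        edges = np.arange(0.0, max_width + bin_width, bin_width)
        combined = pd.concat(all_records.values(), ignore_index=True)
        widths = width_distribution(combined, edges, value="width_nm")

        results: dict = {"distributions": {"width": widths.to_dict()}}
        if len(all_records) >= 2:
            names = sorted(all_records)
            wtest = kruskal_wallis(
                [all_records[n]["width_nm"].to_numpy() for n in names]
            )
            itest = kruskal_wallis(
                [all_records[n]["intensity"].to_numpy() for n in names]
            )
            results["kruskal_wallis"] = {
                "width": asdict(wtest),
                "intensity": asdict(itest),
                "conditions": names,
            }

        p = outdir / "distributions.json"
        p.write_text(json.dumps(results["distributions"], indent=2))
        written.append(p)
        if "kruskal_wallis" in results:
            p = outdir / "stats.json"
            p.write_text(json.dumps(results["kruskal_wallis"], indent=2))
            written.append(p)

        report = {
            "version": __version__,
            "seed": seed,
            "parameters": {
                "reconstruction": recon,
                "segmentation": {**seg, "sigmas": list(seg_params.sigmas)},
                "morphometry": morpho,
                "stats": stats_cfg,
            },
            "conditions": {
                name: {"n_tubules": int(len(df)), **counts.get(name, {})}
                for name, df in all_records.items()
            },
            "results": results.get("kruskal_wallis"),
        }
        p = outdir / "report.json"
        p.write_text(json.dumps(report, indent=2))
        written.append(p)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
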