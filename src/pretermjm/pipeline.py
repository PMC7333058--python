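"""End-to-end orchestration: simulate -> fit -> compare -> predict.

A run is described by a :class:`RunConfig` (loadable from YAML) naming
either input CSVs or a generator configuration, the basis and MCMC
settings, and an output directory.  ``run_pipeline`` writes, under the
output directory:

* cohort CSVs + provenance (when simulated),
* a Table-2-style posterior summary CSV for the selected joint model and
  the time-dependent Cox comparator,
* a Table-3-style association-comparison CSV (association, DIC, pD),
* risk-curve CSVs and figures for selected women,
* a machine-readable run manifest (config hash, seed, versions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import GeneratorConfig
from .data import CohortData
from .joint import JointModel, MCMCSettings, compare_structures
from .prediction import risk_trajectory
from .simulate import generate_cohort
from .tdcox import TimeDependentCox

__all__ = ["RunConfig", "run_pipeline", "read_cohort"]

log = logging.getLogger("pretermjm")

_KNOWN_KEYS = {
    "longitudinal_path",
    "subjects_path",
    "generator",
    "n_interior_knots",
    "associations",
    "chains",
    "warmup",
    "draws",
    "seed",
    "out_dir",
    "predict_women",
    "predict_anchors",
    "log_transform",
    "log_level",
    "on_bad_rhat",
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str
    longitudinal_path: str | None = None
    subjects_path: str | None = None
    generator: dict | None = None
    n_interior_knots: int = 4
    associations: tuple[str, ...] = ("value", "value_slope", "auc")
    chains: int = 2
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    predict_women: tuple = ()
    predict_anchors: tuple = ()
    log_transform: bool = True
    log_level: str = "INFO"
    on_bad_rhat: str = "warn"

    def __post_init__(self) -> None:
        has_files = self.longitudinal_path is not None or self.subjects_path is not None
        has_gen = self.generator is not None
        if has_files == has_gen:
            raise ValueError(
                "exactly one of {input CSV paths, generator config} must be given"
            )
        if has_files and (self.longitudinal_path is None or self.subjects_path is None):
            raise ValueError("both longitudinal_path and subjects_path are required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("associations", "predict_women", "predict_anchors"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_cohort(
    longitudinal_path, subjects_path, log_transform: bool = False
) -> CohortData:
    """Load a cohort from CSVs, optionally log-transforming raw glucose.

    With ``log_transform=True`` the longitudinal file is expected to hold
    a raw-scale ``glucose`` column instead of ``log_glucose``.
    """
    lon = pd.read_csv(longitudinal_path)
    subj = pd.read_csv(subjects_path)
    if log_transform:
        if "glucose" not in lon.columns:
            raise ValueError("log_transform=True requires a 'glucose' column")
        if (lon["glucose"] <= 0).any():
            bad = lon.index[lon["glucose"] <= 0].tolist()[:5]
            raise ValueError(f"non-positive glucose at rows {bad}")
        lon = lon.assign(log_glucose=np.log(lon.pop("glucose")))
    return CohortData(longitudinal=lon, subjects=subj)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("run %s starting (seed=%d)", config.config_hash(), config.seed)

    if config.generator is not None:
        gen = GeneratorConfig.from_dict(config.generator)
        cohort = generate_cohort(gen, seed=config.seed)
        cohort.write(out, stem="cohort")
        log.info(
            "simulated cohort: %d women, %d readings, %.1f%% preterm",
            cohort.n_subjects, cohort.n_readings, 100 * cohort.preterm_fraction(),
        )
    else:
        cohort = read_cohort(
            config.longitudinal_path, config.subjects_path,
            log_transform=False,
        )
        log.info("loaded cohort: %d women, %d readings", cohort.n_subjects, cohort.n_readings)

    settings = MCMCSettings(
        chains=config.chains, warmup=config.warmup, draws=config.draws, seed=config.seed
    )

    table3 = compare_structures(
        cohort,
        n_interior_knots=config.n_interior_knots,
        settings=settings,
        on_bad_rhat=config.on_bad_rhat,
        associations=config.associations,
    )
    table3[["association", "DIC", "pD", "status"]].to_csv(
        out / "association_comparison.csv", index=False
    )
    fits = table3.attrs["fits"]
    ok = table3[table3["status"] == "ok"]
    best_assoc = ok["association"].iloc[0] if not ok.empty else None

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "best_association": best_assoc,
        "outputs": ["association_comparison.csv"],
    }

    if best_assoc is not None:
        best = fits[best_assoc]
        summ = best.summary().reset_index()
        summ.insert(0, "submodel", [
            "longitudinal" if not p.startswith(("shape", "phi", "alpha")) else "event"
            for p in summ["param"]
        ])
        summ.to_csv(out / "joint_model_summary.csv", index=False)
        best.save(out / f"posterior_{best_assoc}.npz")
        manifest["outputs"] += ["joint_model_summary.csv", f"posterior_{best_assoc}.npz"]

        td = TimeDependentCox(cohort).fit("semiparametric")
        td_out = td.summary().reset_index(names="param")
        td_out["dic_analog"] = td.dic_analog
        td_out.to_csv(out / "tdcox_summary.csv", index=False)
        manifest["outputs"].append("tdcox_summary.csv")

        for sid in config.predict_women:
            hist = cohort.readings_for(sid)[["day", "log_glucose"]]
            srow = cohort.subject(sid)
            covs = {
                "age_lmp": srow["age_lmp"],
                "age_onset": srow["age_onset"],
                "nephropathy": srow["nephropathy"],
            }
            anchors = config.predict_anchors or (float(hist["day"].median()),)
            anchors = [a for a in anchors if a < 259 and (hist["day"] <= a).any()]
            curves = risk_trajectory(
                best, hist, covs, anchors, draws=300, seed=config.seed
            )
            frames = pd.concat([c.to_frame() for c in curves])
            fname = f"risk_woman_{sid}.csv"
            frames.to_csv(out / fname, index=False)
            manifest["outputs"].append(fname)
            try:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(6, 4))
                ax.errorbar(
                    [c.anchor_day for c in curves],
                    [c.risk_at_threshold for c in curves],
                    yerr=[
                        [c.risk_at_threshold - c.lower[-1] for c in curves],
                        [c.upper[-1] - c.risk_at_threshold for c in curves],
                    ],
                    marker="o",
                )
                ax.set_xlabel("anchor gestational day (last reading used)")
                ax.set_ylabel("P(preterm | event-free at anchor)")
                ax.set_ylim(0, 1)
                fig.savefig(out / f"risk_woman_{sid}.png", dpi=100)
                plt.close(fig)
                manifest["outputs"].append(f"risk_woman_{sid}.png")
            except Exception as exc:  # noqa: BLE001 - plotting is best-effort
                log.warning("figure for woman %s failed: %s", sid, exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("run complete: %s", out)
    return out


def _versions() -> dict:
    import arviz
    import lifelines
    import matplotlib
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "arviz": arviz.__version__,
        "lifelines": lifelines.__version__,
        "matplotlib": matplotlib.__version__,
    }
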