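"""Configuration, dataset I/O and end-to-end orchestration.

A run is described by a single YAML document (model, dataset, basis, noise,
prior, tau strategy, sampler, outputs).  ``run_pipeline`` executes the
configured stages in order — tau selection by L-curve if requested, MAP,
MCMC initialised at the MAP, posterior summaries — and writes every artefact
(tables as CSV, metadata as YAML, plots as PNG) into the output directory,
including a fully resolved copy of the configuration so runs are
self-documenting and regenerable from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import synthgen
from .basis import BasisSet, InputFunction, bspline_basis, kl_basis, piecewise_constant_basis
from .diagnostics import bioavailability, effective_sample_size, summarize_input, summarize_output
from .dynamics import get_system
from .estimators import BayesianInputEstimator, LCurveSelector, MAPInputEstimator
from .objective import NoiseModel


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Time-series I/O
# ---------------------------------------------------------------------------


def read_timeseries(path):
    """Read a delimited table with columns time, value [, series].

    Lines starting with '#' are treated as a self-describing header block.
    Times must be strictly increasing; violations are reported with the
    offending time value.
    """
    path = Path(path)
    content = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if len(content) < 2:  # need a header and at least one row
        raise FormatError(f"{path}: empty dataset")
    try:
        df = pd.read_csv(path, comment="#", sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty dataset") from None
    cols = {c.lower().strip(): c for c in df.columns}
    if "time" not in cols or "value" not in cols:
        raise FormatError(f"{path}: expected columns 'time' and 'value', got {list(df.columns)}")
    t = pd.to_numeric(df[cols["time"]], errors="coerce")
    v = pd.to_numeric(df[cols["value"]], errors="coerce")
    bad = t.isna() | v.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.values)[0]) + 2  # header is line 1
        raise FormatError(f"{path}: unparseable numeric value at line {line}")
    dt = np.diff(t.values)
    if np.any(dt <= 0):
        i = int(np.flatnonzero(dt <= 0)[0])
        kind = "duplicated" if dt[i] == 0 else "non-monotone"
        raise FormatError(f"{path}: {kind} time {float(t.values[i + 1])}")
    out = pd.DataFrame({"time": t.values, "value": v.values})
    if "series" in cols:
        out["series"] = df[cols["series"]].values
    return out


def write_timeseries(path, times, values, header: dict | None = None):
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        pd.DataFrame({"time": times, "value": values}).to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "scale": "linear",
    "noise": {"kind": "additive", "sigma": 1.0},
    "prior": {"kind": "derivative", "penalty_order": 2},
    "tau": {"strategy": "fixed", "value": 1.0, "a0": 0.001, "b0": 0.001},
    "sampler": None,
    "dose": None,
    "outputs": "results",
}


@dataclass
class RunConfig:
    model: dict
    dataset: dict
    basis: dict
    scale: str = "linear"
    noise: dict = field(default_factory=lambda: dict(_DEFAULTS["noise"]))
    prior: dict = field(default_factory=lambda: dict(_DEFAULTS["prior"]))
    tau: dict = field(default_factory=lambda: dict(_DEFAULTS["tau"]))
    sampler: Optional[dict] = None
    dose: Optional[float] = None
    outputs: str = "results"

    def __post_init__(self):
        if self.prior.get("kind") == "entropy" and self.basis.get("kind") != "piecewise_constant":
            raise ValueError("the entropy prior requires a piecewise-constant basis")
        if self.tau.get("strategy") == "bayes" and self.sampler is None:
            raise ValueError("tau strategy 'bayes' requires a sampler")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        merged = {**_DEFAULTS, **raw}
        for key in ("noise", "prior", "tau"):
            merged[key] = {**_DEFAULTS[key], **(raw.get(key) or {})}
        return cls(
            model=merged["model"],
            dataset=merged["dataset"],
            basis=merged["basis"],
            scale=merged["scale"],
            noise=merged["noise"],
            prior=merged["prior"],
            tau=merged["tau"],
            sampler=merged.get("sampler"),
            dose=merged.get("dose"),
            outputs=merged.get("outputs", "results"),
        )

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def build_basis(cfg: dict, times, t0: float) -> BasisSet:
    """Materialise the configured basis on the data horizon."""
    kind = cfg.get("kind", "karhunen_loeve")
    domain = (float(t0), float(np.max(times)))
    if kind in ("kl", "karhunen_loeve"):
        return kl_basis(
            penalty_order=int(cfg.get("penalty_order", 1)),
            n_basis=int(cfg.get("n_basis", 20)),
            domain=domain,
            grid_size=int(cfg.get("grid_size", 400)),
            augmentation=cfg.get("augmentation", "none"),
        )
    if kind == "bspline":
        bp = cfg.get("breakpoints")
        if bp is None:
            bp = np.unique(np.concatenate([[t0], np.asarray(times, dtype=float)]))
        return bspline_basis(bp, degree=int(cfg.get("degree", 3)))
    if kind == "piecewise_constant":
        return piecewise_constant_basis(int(cfg.get("n", 100)), domain)
    raise ValueError(f"unknown basis kind '{kind}'")


def load_dataset(cfg: dict, system):
    """Load a measurement table from disk or synthesise a built-in design."""
    if "path" in cfg:
        df = read_timeseries(cfg["path"])
        return df["time"].values, df["value"].values, None
    design = cfg.get("synthetic")
    seed = int(cfg.get("seed", 0))
    if design in ("case1_low", "case1_high"):
        dose = 20.0 if design == "case1_low" else 1500.0
        sigma = cfg.get("sigma", synthgen.CASE1_SIGMA["low" if design == "case1_low" else "high"])
        ds = synthgen.make_case1_dataset(system, dose, sigma, seed)
    elif design == "case2_group":
        ds = synthgen.make_case2_dataset(system, seed, sigma=cfg.get("sigma", synthgen.CASE2_SIGMA))
    else:
        raise ValueError(f"unknown synthetic design '{design}'")
    return ds.times, ds.values, ds


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, seed: Optional[int] = None, make_plots: bool = True) -> dict:
    """Execute the configured stages and write artefacts; returns a bundle."""
    outdir = Path(config.outputs)
    outdir.mkdir(parents=True, exist_ok=True)
    log = []
    bundle = {}

    def note(msg):
        log.append(msg)

    try:
        system = get_system(config.model["name"], config.model.get("params"))
        if config.model.get("x0") is not None:
            system = system.with_x0(config.model["x0"])
        times, values, ds = load_dataset(config.dataset, system)
        note(f"dataset: n={times.size} on [{times[0]}, {times[-1]}]")
        basis = build_basis(config.basis, times, system.t0)
        note(f"basis: {basis.kind} n_total={basis.n_total}")

        common = dict(
            system=system,
            basis=basis,
            scale=config.scale,
            noise=config.noise["kind"],
            sigma=float(config.noise["sigma"]),
            penalty_order=int(config.prior.get("penalty_order", 2)),
        )

        # --- tau selection ------------------------------------------------
        strategy = config.tau.get("strategy", "fixed")
        tau_value = float(config.tau.get("value", 1.0))
        if strategy == "l_curve":
            sel = LCurveSelector(tau_grid=config.tau.get("grid"), **common).fit(times, values)
            tau_value = sel.tau_
            bundle["lcurve"] = sel.result_
            sel.result_.to_table().to_csv(outdir / "lcurve.csv", index=False)
            note(f"l_curve: corner tau = {tau_value:.4g}, selected {sel.selected_taus_}")
            if make_plots:
                _plot_lcurve(sel.result_, outdir / "lcurve.png")

        # --- MAP ------------------------------------------------------------
        map_est = MAPInputEstimator(
            tau=tau_value,
            method=config.model.get("map_method", "shooting"),
            prior_kind=config.prior.get("kind", "derivative"),
            **common,
        ).fit(times, values)
        bundle["map"] = map_est.result_
        _write_map_result(map_est.result_, tau_value, outdir / "map_result.yaml")
        note(
            f"MAP ({map_est.result_.method}): objective={map_est.objective_:.6g} "
            f"E_D={map_est.E_D_:.6g} E_W={map_est.E_W_:.6g} converged={map_est.converged_}"
        )

        # --- MCMC -----------------------------------------------------------
        if config.sampler:
            samp = dict(config.sampler)
            chain_seed = int(seed if seed is not None else samp.get("seed", 0))
            tau_prior = None
            if strategy == "bayes":
                tau_prior = (float(config.tau.get("a0", 0.001)), float(config.tau.get("b0", 0.001)))
            bay = BayesianInputEstimator(
                tau=tau_value,
                tau_prior=tau_prior,
                scheme=samp.get("scheme", "smmala_gibbs"),
                n_samples=int(samp.get("n_samples", 5000)),
                epsilon=float(samp.get("epsilon", 1.0)),
                random_state=chain_seed,
                **common,
            ).fit(times, values)
            bundle["chain"] = bay.chain_
            bay.chain_.to_frame().to_csv(outdir / "chain.csv", index=False)
            meta = {
                "seed": chain_seed,
                "scheme": bay.chain_.sampler,
                "n_samples": bay.chain_.n_samples,
                "burn_in": bay.chain_.burn_in,
                "acceptance_rate": bay.chain_.acceptance_rate(),
                "n_failures": bay.chain_.n_failures,
                "ess_log_posterior": effective_sample_size(bay.chain_.log_posts[bay.chain_.burn_in :]),
            }
            with open(outdir / "chain_meta.yaml", "w") as fh:
                yaml.safe_dump(meta, fh)
            note(f"chain: acc={meta['acceptance_rate']:.3f} ESS(logp)={meta['ess_log_posterior']:.1f}")

            grid = np.linspace(basis.domain[0], basis.domain[1], 201)
            u_sum = bay.input_summary(grid)
            y_sum = bay.output_summary(grid, thin=max(1, bay.samples_.shape[0] // 200))
            u_sum.to_frame().to_csv(outdir / "input_summary.csv", index=False)
            y_sum.to_frame().to_csv(outdir / "output_summary.csv", index=False)
            bundle["input_summary"] = u_sum
            bundle["output_summary"] = y_sum
            if make_plots:
                _plot_band(u_sum, None, None, "input u(t)", outdir / "input_band.png")
                _plot_band(y_sum, times, values, "predicted output", outdir / "output_band.png")

            if config.dose:
                F = bay.bioavailability(float(config.dose))
                bundle["bioavailability"] = F
                pd.DataFrame({"F": F["samples"]}).to_csv(outdir / "bioavailability.csv", index=False)
                note(f"bioavailability: mean={F['mean']:.4f} [{F['lower95']:.4f}, {F['upper95']:.4f}]")
                if make_plots:
                    _plot_density(F["samples"], outdir / "bioavailability.png")

        with open(outdir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh)
    except Exception as exc:
        with open(outdir / "error_report.txt", "w") as fh:
            fh.write(f"pipeline failed: {exc}\n")
            fh.write("completed stages:\n" + "\n".join(log) + "\n")
        raise
    finally:
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write("\n".join(log) + "\n")
    bundle["log"] = log
    return bundle


def _write_map_result(res, tau, path):
    doc = {
        "method": res.method,
        "tau": float(tau),
        "objective": float(res.objective),
        "E_D": float(res.E_D),
        "E_W": float(res.E_W),
        "converged": bool(res.converged),
        "n_iterations": int(res.n_iterations),
        "message": res.message,
        "theta_hat": [float(v) for v in res.theta_hat],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def _plot_lcurve(res, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(res.E_W_curve, res.E_D_curve, "o-", ms=3)
    ax.loglog(
        res.E_W_curve[res.corner_index], res.E_D_curve[res.corner_index], "rs", label="corner"
    )
    ax.set_xlabel("E_W (regularity)")
    ax.set_ylabel("E_D (misfit)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_band(summary, times, values, ylabel, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(summary.grid, summary.lower95, summary.upper95, alpha=0.3, label="95% CI")
    ax.plot(summary.grid, summary.mean, label="posterior mean")
    if times is not None:
        ax.plot(times, values, "ko", ms=3, label="measurements")
    ax.set_xlabel("time")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_density(samples, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(5, 4))
    kde = gaussian_kde(samples)
    x = np.linspace(np.min(samples), np.max(samples), 400)
    ax.plot(x, kde(x))
    ax.axvline(np.mean(samples), color="k", label="mean")
    lo, hi = np.percentile(samples, [2.5, 97.5])
    ax.axvline(lo, color="k", ls="--")
    ax.axvline(hi, color="k", ls="--", label="95% CI")
    ax.set_xlabel("bioavailability F")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
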