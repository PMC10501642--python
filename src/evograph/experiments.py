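"""Config-driven, desk-scale reproductions of the figure-level experiments.

Each experiment id maps to one study design:

``fig2b``
    steady-state mean fitness vs mutation rate per graph family, with the
    analytic low-mu reference mean and the mutation-rate threshold;
``fig2c``
    exact neutral temperature-initialised fixation time vs ``N`` per
    family, with Gillespie estimates for the star families;
``fig3``
    the mu = 1 self-looped complete reference: ensemble mean/sd vs the
    closed form;
``fig4``
    node-wise time-averaged fitness on the self-looped weighted star and
    the self-looped directed line at mu = 1;
``fig5``
    steady-state mean per (graph, sigma) with the truncated Gaussian
    kernel;
``fig10``
    the high-mu universality scan over non-self-looped graphs against the
    self-looped complete reference.

Defaults run at reduced scale (200 replicates, ``10^4 * N`` steps); the
full-scale settings are plain config values.  Outputs are RFC-4180 CSV
tables plus a JSON manifest carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chains import star_chain
from .gillespie import gillespie_ensemble
from .graphs import build_family
from .kernels import MutationKernel, kernel_from_spec
from .moran import run_mutation_selection
from .steady_state import high_mu_selflooped_complete, low_mu_mean_for_family
from .threshold import mu_threshold, tau_T_functions

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]

_DEF_KERNEL = {"kind": "uniform", "f_min": 0.1, "f_max": 10.0}

#: families shown on the mutation-rate sweep
_FIG2B_FAMILIES = (
    "selflooped_weighted_star",
    "star",
    "complete",
    "cycle",
    "selflooped_directed_line",
)
_FIG10_FAMILIES = (
    "complete",
    "cycle",
    "star",
    "molded_directed_line",
    "modified_burst",
    "selflooped_complete",
)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    experiment: str
    seed: int
    out_dir: str = "results"
    replicates: int = 200
    N: int = 10
    N_list: list[int] = field(default_factory=list)
    mu_grid: list[float] = field(default_factory=lambda: [1e-3, 1e-2, 1e-1, 1.0])
    sigma_list: list[float] = field(default_factory=lambda: [0.1, 1.0, 10.0])
    families: list[str] = field(default_factory=list)
    kernel: dict = field(default_factory=lambda: dict(_DEF_KERNEL))
    n_steps: int | None = None  # default 10^4 * N
    force: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {sorted(EXPERIMENTS)}"
            )
        if self.replicates < 2:
            raise ValueError("replicates must be at least 2 for ensemble statistics")
        if self.seed is None:
            raise ValueError("a seed is required (reproducibility contract)")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data.update(overrides)
        return cls(**data)

    def steps(self, N: int | None = None) -> int:
        return int(self.n_steps or 10_000 * (N or self.N))

    def make_kernel(self, sigma: float | None = None) -> MutationKernel:
        spec = dict(self.kernel)
        if sigma is not None:
            spec.update(kind="truncated_gaussian", sigma=sigma)
        return kernel_from_spec(spec)

    def canonical_json(self) -> str:
        # operational fields (output location, overwrite flag) do not alter
        # the science and stay out of the hash
        data = {k: v for k, v in asdict(self).items() if k not in ("out_dir", "force")}
        return json.dumps(data, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _sweep_mean(family, N, kernel, mu, steps, reps, seed):
    g = build_family(family, N)
    s = run_mutation_selection(g, kernel, mu, steps, reps, seed)
    return s


def _run_fig2b(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    k = cfg.make_kernel()
    families = cfg.families or list(_FIG2B_FAMILIES)
    rows, refs = [], []
    for fi, fam in enumerate(families):
        for mi, mu in enumerate(cfg.mu_grid):
            s = _sweep_mean(
                fam, cfg.N, k, float(mu), cfg.steps(), cfg.replicates,
                cfg.seed + 1000 * fi + 10_000 * mi,
            )
            rows.append(
                {"family": fam, "mu": mu, "mean_fitness": s.ensemble_mean,
                 "se": s.ensemble_se, "replicates": cfg.replicates}
            )
        th = mu_threshold(fam, cfg.N, k.f_min, k.f_max)
        refs.append(
            {"family": fam,
             "low_mu_mean": low_mu_mean_for_family(fam, cfg.N, k),
             "mu_th": th.mu_th, "argmax_r": th.argmax_r}
        )
    return {"fig2b": pd.DataFrame(rows), "fig2b_reference": pd.DataFrame(refs)}


def _run_fig2c(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    families = cfg.families or list(_FIG2B_FAMILIES)
    N_list = cfg.N_list or [10, 20, 40]
    rows = []
    for fam in families:
        for N in N_list:
            tau = tau_T_functions(fam, N)[0](1.0)
            row = {"family": fam, "N": N, "tau_exact": tau,
                   "tau_gillespie": np.nan, "tau_gillespie_se": np.nan}
            if fam in ("star", "selflooped_weighted_star"):
                n = N - 1
                lam, delta = (1.0, 1.0) if fam == "star" else (1.0 / n, 1.0 / n**2)
                est = gillespie_ensemble(
                    star_chain(n, lam, delta, 1.0), "temperature",
                    min(cfg.replicates, 500), cfg.seed + N,
                )
                row.update(tau_gillespie=est.tau_T, tau_gillespie_se=est.tau_T_se)
            rows.append(row)
    return {"fig2c": pd.DataFrame(rows)}


def _run_fig3(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    k = cfg.make_kernel()
    N_list = cfg.N_list or [10, 20]
    rows = []
    for Ni, N in enumerate(N_list):
        s = _sweep_mean("selflooped_complete", N, k, 1.0, cfg.steps(N),
                        cfg.replicates, cfg.seed + Ni)
        ref = high_mu_selflooped_complete(k.f_min, k.f_max, N)
        rows.append(
            {"N": N, "mean_fitness": s.ensemble_mean, "sd": s.ensemble_sd,
             "se": s.ensemble_se, "analytic_mean": ref.mean, "analytic_sd": ref.sd,
             "replicates": cfg.replicates}
        )
    return {"fig3": pd.DataFrame(rows)}


def _run_fig4(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    k = cfg.make_kernel()
    rows = []
    for fi, fam in enumerate(("selflooped_weighted_star", "selflooped_directed_line")):
        s = _sweep_mean(fam, cfg.N, k, 1.0, cfg.steps(), cfg.replicates, cfg.seed + fi)
        node_avg = s.node_time_average()
        for node, avg in enumerate(node_avg):
            rows.append({"family": fam, "node": node, "avg_fitness": float(avg)})
        rows.append({"family": fam, "node": -1, "avg_fitness": float(node_avg.mean())})
    return {"fig4": pd.DataFrame(rows)}


def _run_fig5(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    families = cfg.families or [
        "complete", "selflooped_complete", "cycle", "selflooped_cycle",
        "star", "selflooped_star", "molded_directed_line", "selflooped_directed_line",
    ]
    rows = []
    for si, sigma in enumerate(cfg.sigma_list):
        k = cfg.make_kernel(sigma=float(sigma))
        for fi, fam in enumerate(families):
            s = _sweep_mean(fam, cfg.N, k, 1.0, cfg.steps(), cfg.replicates,
                            cfg.seed + 100 * si + fi)
            rows.append({"family": fam, "sigma": sigma,
                         "mean_fitness": s.ensemble_mean, "se": s.ensemble_se})
    return {"fig5": pd.DataFrame(rows)}


def _run_fig10(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    k = cfg.make_kernel()
    families = cfg.families or list(_FIG10_FAMILIES)
    N_list = cfg.N_list or [cfg.N]
    rows = []
    for Ni, N in enumerate(N_list):
        for fi, fam in enumerate(families):
            s = _sweep_mean(fam, N, k, 1.0, cfg.steps(N), cfg.replicates,
                            cfg.seed + 100 * Ni + fi)
            rows.append({"family": fam, "N": N,
                         "mean_fitness": s.ensemble_mean, "se": s.ensemble_se})
    return {"fig10": pd.DataFrame(rows)}


EXPERIMENTS = {
    "fig2b": _run_fig2b,
    "fig2c": _run_fig2c,
    "fig3": _run_fig3,
    "fig4": _run_fig4,
    "fig5": _run_fig5,
    "fig10": _run_fig10,
}


def run_experiment(cfg: ExperimentConfig) -> dict[str, Path]:
    """Run one experiment and write its CSV tables plus a JSON manifest.

    Identical config and seed produce byte-identical outputs.  Raises if the
    output directory already holds a manifest for this experiment and
    ``force`` is not set.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / f"{cfg.experiment}_manifest.json"
    if manifest_path.exists() and not cfg.force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    tables = EXPERIMENTS[cfg.experiment](cfg)
    written: dict[str, Path] = {}
    h = cfg.config_hash()
    for name, df in tables.items():
        df = df.copy()
        df["config_hash"] = h
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\r\n")
        written[name] = path
    manifest = {
        "experiment": cfg.experiment,
        "config": asdict(cfg),
        "config_hash": h,
        "seed": cfg.seed,
        "versions": {"evograph": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "outputs": sorted(str(p) for p in written.values()),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = manifest_path
    return written
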