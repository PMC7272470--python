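"""Config-driven computational experiments with deterministic CSV/JSON output.

Each experiment kind mirrors one of the standard analyses of the decoy
model: Fano-factor sweeps over decoy number and affinity, constant-mean
heatmaps (retuning the burst frequency to pin the mean free TF count),
two-decoy mixture heatmaps, autocorrelation comparisons, target-gene noise
propagation, and the twin comparison of a high-affinity/low-abundance
versus low-affinity/high-abundance decoy pool.

Every run writes ``<name>.csv`` (data, deterministic byte-for-byte for a
fixed config and seed) and ``<name>_meta.json`` (config echo, hash, seed,
version, timestamp).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytics
from .bursts import BurstDistribution
from .errors import InvalidParameterError
from .lna import build_lna_system, lna_fano, lna_moments, lna_autocorrelation
from .model import DEFAULT_KB, DecoySpecies, TFDecoyModel, TargetGene
from .cme import cme_steady_state
from .ssa import simulate_replicates
from .stats import autocorrelation, flux_balance, stationary_moments

EXPERIMENT_KINDS = ("fano-vs-N", "fixed-mean-heatmap", "mixture-heatmap",
                    "autocorr", "target-noise", "twin-comparison",
                    "oracle-check")

try:
    from importlib.metadata import version as _pkg_version
    _VERSION = _pkg_version("decoysim")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()


def _write_outputs(out_dir: Path, name: str, frame: pd.DataFrame,
                   config: dict, seed: int) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"
    frame.to_csv(csv_path, index=False, float_format="%.10g")
    meta = {
        "config": config,
        "config_sha256": _config_hash(config),
        "seed": seed,
        "package_version": _VERSION,
        "created": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / f"{name}_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return csv_path


def _tf_block(config: dict) -> tuple[float, BurstDistribution, float, float]:
    """(k_x, burst, gamma_f, beta) from the config's ``tf`` block."""
    tf = config.get("tf", {})
    burst = BurstDistribution.from_dict(
        tf.get("burst", {"kind": "geometric", "mean": 20.0}))
    gamma_f = tf.get("gamma_f", 1.0)
    if "beta" in tf:
        beta = tf["beta"]
    else:
        beta = tf.get("gamma_b", gamma_f) / gamma_f
    return tf.get("k_x", 10.0), burst, gamma_f, beta


def _grid(config: dict, key: str, default_lo: float, default_hi: float,
          default_n: int, log: bool = True) -> np.ndarray:
    spec = config.get(key)
    if spec is None:
        if log:
            return np.geomspace(default_lo, default_hi, default_n)
        return np.linspace(default_lo, default_hi, default_n)
    if isinstance(spec, dict):
        fn = np.geomspace if spec.get("log", log) else np.linspace
        return fn(spec["lo"], spec["hi"], spec.get("n", default_n))
    return np.asarray(spec, dtype=float)


# --------------------------------------------------------------------- #
# experiment implementations


def _fano_vs_n(config: dict, seed: int) -> pd.DataFrame:
    k_x, burst, gamma_f, beta = _tf_block(config)
    x_f0 = analytics.no_decoy_mean(k_x, burst.mean, gamma_f)
    f0 = analytics.no_decoy_fano(burst)
    n_values = _grid(config, "N_values", 1, 1e4, 41)
    kd_values = _grid(config, "kd_values", 1e-1, 1e3, 4)
    with_lna = config.get("with_lna", False)
    with_ssa = config.get("with_ssa", False)
    k_b = config.get("k_b", DEFAULT_KB)
    rows = []
    for k_d in kd_values:
        for n in n_values:
            sol = analytics.mean_with_decoys(x_f0, n, k_d, beta)
            row = {
                "k_d": k_d, "N": n, "beta": beta, "k_x": k_x,
                "burst_mean": burst.mean, "gamma_f": gamma_f,
                "x_f0": x_f0, "fano0": f0,
                "analytic_mean_xf": sol.x_free,
                "analytic_mean_xb": sol.x_bound,
                "bound_fraction": sol.bound_fraction,
                "analytic_fano_xf": analytics.fano_with_decoys(
                    x_f0, f0, n, k_d, beta),
                "lna_mean_xf": np.nan, "lna_fano_xf": np.nan,
                "ssa_mean_xf": np.nan, "ssa_fano_xf": np.nan,
                "ssa_se_fano": np.nan,
            }
            model = TFDecoyModel(
                k_x=k_x, burst=burst, gamma_f=gamma_f,
                gamma_b=beta * gamma_f,
                decoys=(DecoySpecies.from_kd(int(round(n)), k_d, k_b),))
            if with_lna:
                system, sigma = lna_moments(model)
                row["lna_mean_xf"] = system.fixed_point[0]
                row["lna_fano_xf"] = sigma[0, 0] / system.fixed_point[0]
            if with_ssa:
                trajs = simulate_replicates(
                    model, t_end=config.get("t_end", 500.0),
                    n_replicates=config.get("replicates", 4), seed=seed)
                summary = stationary_moments(trajs)
                row["ssa_mean_xf"] = summary["x_f"]["mean"]
                row["ssa_fano_xf"] = summary["x_f"]["fano"]
                row["ssa_se_fano"] = summary["x_f"]["se_fano"]
                seed += len(trajs)
            rows.append(row)
    return pd.DataFrame(rows)


def _fixed_mean_heatmap(config: dict, seed: int) -> pd.DataFrame:
    _, burst, gamma_f, beta = _tf_block(config)
    mean_target = config.get("mean_target", 20.0)
    f0 = analytics.no_decoy_fano(burst)
    n_values = _grid(config, "N_values", 1, 1e4, 31)
    kd_values = _grid(config, "kd_values", 1e-1, 1e3, 31)
    rows = []
    for k_d in kd_values:
        for n in n_values:
            k_x = analytics.required_kx_for_mean(
                mean_target, n, k_d, beta, burst.mean, gamma_f)
            x_f0 = analytics.no_decoy_mean(k_x, burst.mean, gamma_f)
            fano = analytics.fano_with_decoys(x_f0, f0, n, k_d, beta)
            rows.append({
                "k_d": k_d, "N": n, "beta": beta, "mean_target": mean_target,
                "k_x": k_x, "x_f0": x_f0, "fano0": f0,
                "analytic_fano_xf": fano,
                "fano_normalized": fano / f0,
            })
    return pd.DataFrame(rows)


def _mixture_heatmap(config: dict, seed: int) -> pd.DataFrame:
    k_x, burst, gamma_f, beta = _tf_block(config)
    f0 = analytics.no_decoy_fano(burst)
    k_b = config.get("k_b", 1000.0)
    d1 = config.get("decoy1", {"N": 200, "k_d": 1.0})
    mode = config.get("mode", "N2-kd2")
    rows = []
    if mode == "N2-kd2":
        n2_values = _grid(config, "N2_values", 1, 1e4, 25)
        kd2_values = _grid(config, "kd2_values", 1e-1, 1e3, 25)
        cases = [(d1["N"], d1["k_d"], n2, kd2)
                 for kd2 in kd2_values for n2 in n2_values]
    elif mode == "N1-N2":
        kd2 = config.get("k_d2", 100.0)
        n1_values = _grid(config, "N1_values", 1, 1e4, 25)
        n2_values = _grid(config, "N2_values", 1, 1e4, 25)
        cases = [(n1, d1["k_d"], n2, kd2)
                 for n1 in n1_values for n2 in n2_values]
    else:
        raise InvalidParameterError(f"unknown mixture mode {mode!r}")
    for n1, kd1, n2, kd2 in cases:
        model = TFDecoyModel(
            k_x=k_x, burst=burst, gamma_f=gamma_f, gamma_b=beta * gamma_f,
            decoys=(DecoySpecies.from_kd(int(round(n1)), kd1, k_b),
                    DecoySpecies.from_kd(int(round(n2)), kd2, k_b)))
        fano = lna_fano(model)["x_f"]
        rows.append({
            "N1": n1, "k_d1": kd1, "N2": n2, "k_d2": kd2, "beta": beta,
            "k_b": k_b, "fano0": f0, "lna_fano_xf": fano,
            "fano_normalized": fano / f0,
        })
    return pd.DataFrame(rows)


def _autocorr(config: dict, seed: int) -> pd.DataFrame:
    _, burst, gamma_f, beta_default = _tf_block(config)
    mean_target = config.get("mean_target", 20.0)
    k_b = config.get("k_b", DEFAULT_KB)
    t_end = config.get("t_end", 300.0)
    n_reps = config.get("replicates", 8)
    dt = config.get("dt", 0.02 / gamma_f)
    max_lag = config.get("max_lag", 5.0 / gamma_f)
    variants = config.get("variants", [
        {"label": "no-decoy"},
        {"label": "beta0", "N": 100, "k_d": 1.0, "beta": 0.0},
        {"label": "beta1", "N": 100, "k_d": 1.0, "beta": 1.0},
    ])
    rows = []
    for variant in variants:
        n = variant.get("N", 0)
        if n == 0:
            k_x = gamma_f * mean_target / burst.mean
            model = TFDecoyModel(k_x=k_x, burst=burst, gamma_f=gamma_f,
                                 gamma_b=0.0)
        else:
            k_d = variant["k_d"]
            beta = variant.get("beta", beta_default)
            k_x = analytics.required_kx_for_mean(
                mean_target, n, k_d, beta, burst.mean, gamma_f)
            model = TFDecoyModel(
                k_x=k_x, burst=burst, gamma_f=gamma_f,
                gamma_b=beta * gamma_f,
                decoys=(DecoySpecies.from_kd(int(n), k_d, k_b),))
        trajs = simulate_replicates(model, t_end=t_end, n_replicates=n_reps,
                                    seed=seed, sampling="grid", grid_dt=dt)
        seed += n_reps
        curve = autocorrelation(trajs, max_lag=max_lag)
        for tau, r, se in zip(curve.lags, curve.r, curve.se):
            rows.append({"variant": variant["label"], "tau": tau, "R": r,
                         "se": se, "exp_reference": np.exp(-gamma_f * tau)})
    return pd.DataFrame(rows)


def _target_noise(config: dict, seed: int) -> pd.DataFrame:
    _, burst, gamma_f, _ = _tf_block(config)
    mean_target = config.get("mean_target", 20.0)
    f0 = analytics.no_decoy_fano(burst)
    tgt = config.get("target", {"k_y": 10.0, "gamma_y": 1.0,
                                "burst": {"kind": "degenerate", "size": 1}})
    by = BurstDistribution.from_dict(tgt["burst"])
    k_d = config.get("k_d", 1.0)
    n_values = _grid(config, "N_values", 1, 1e4, 31)
    beta_values = config.get("beta_values", [0.0, 1.0, 5.0])
    rows = []
    for beta in beta_values:
        for n in n_values:
            k_x = analytics.required_kx_for_mean(
                mean_target, n, k_d, beta, burst.mean, gamma_f)
            x_f0 = analytics.no_decoy_mean(k_x, burst.mean, gamma_f)
            fxf = analytics.fano_with_decoys(x_f0, f0, n, k_d, beta)
            fy = analytics.target_fano(
                x_f0, f0, n, k_d, beta, tgt["k_y"], by.mean,
                by.second_moment, tgt["gamma_y"], gamma_f)
            rows.append({
                "beta": beta, "N": n, "k_d": k_d, "k_x": k_x,
                "mean_target": mean_target,
                "analytic_fano_xf": fxf, "analytic_fano_y": fy,
                "propagation_ratio": fy / fxf,
            })
    return pd.DataFrame(rows)


def _twin_comparison(config: dict, seed: int) -> pd.DataFrame:
    k_x, burst, gamma_f, beta = _tf_block(config)
    k_b = config.get("k_b", DEFAULT_KB)
    scenarios = config.get("scenarios", [
        {"label": "high-affinity", "N": 245, "k_d": 1.0,
         "t_end": 1000.0, "replicates": 6},
        {"label": "low-affinity", "N": 1400, "k_d": 100.0,
         "t_end": 200.0, "replicates": 4},
    ])
    burn_in = config.get("burn_in", 20.0)
    rows = []
    for sc in scenarios:
        model = TFDecoyModel(
            k_x=k_x, burst=burst, gamma_f=gamma_f, gamma_b=beta * gamma_f,
            decoys=(DecoySpecies.from_kd(int(sc["N"]), sc["k_d"], k_b),))
        trajs = simulate_replicates(
            model, t_end=sc.get("t_end", 500.0),
            n_replicates=sc.get("replicates", 4), seed=seed, burn_in=burn_in)
        seed += len(trajs)
        summary = stationary_moments(trajs)
        fb = flux_balance(summary, model)
        xf = summary["x_f"]
        rows.append({
            "scenario": sc["label"], "N": sc["N"], "k_d": sc["k_d"],
            "beta": beta, "k_b": k_b,
            "mean_xf": xf["mean"], "se_mean_xf": xf["se_mean"],
            "var_xf": xf["variance"], "fano_xf": xf["fano"],
            "se_fano_xf": xf["se_fano"],
            "flux_production": fb["production"], "flux_drain": fb["drain"],
            "flux_se": fb["se"],
        })
    return pd.DataFrame(rows)


def _oracle_check(config: dict, seed: int) -> pd.DataFrame:
    model = TFDecoyModel.from_dict(config["model"])
    x_max = config.get("x_max", 60)
    y_max = config.get("y_max")
    oracle = cme_steady_state(model, x_max, y_max)
    trajs = simulate_replicates(
        model, t_end=config.get("t_end", 2000.0),
        n_replicates=config.get("replicates", 10), seed=seed)
    summary = stationary_moments(trajs)
    system, sigma = lna_moments(model)
    rows = []
    for i, label in enumerate(model.species_labels):
        rows.append({
            "species": label,
            "oracle_mean": oracle.mean[i], "oracle_fano": oracle.fano[i],
            "ssa_mean": summary.mean[i], "ssa_se_mean": summary.se_mean[i],
            "ssa_fano": summary.fano[i], "ssa_se_fano": summary.se_fano[i],
            "lna_mean": system.fixed_point[i],
            "lna_fano": (sigma[i, i] / system.fixed_point[i]
                         if system.fixed_point[i] > 0 else np.nan),
            "oracle_leak": oracle.leak,
        })
    return pd.DataFrame(rows)


_DISPATCH = {
    "fano-vs-N": _fano_vs_n,
    "fixed-mean-heatmap": _fixed_mean_heatmap,
    "mixture-heatmap": _mixture_heatmap,
    "autocorr": _autocorr,
    "target-noise": _target_noise,
    "twin-comparison": _twin_comparison,
    "oracle-check": _oracle_check,
}


def run_experiment(config: dict, out_dir: str | Path, seed: int = 1
                   ) -> Path:
    """Run one named experiment; returns the path of the written CSV."""
    kind = config.get("experiment")
    if kind not in _DISPATCH:
        raise InvalidParameterError(
            f"unknown experiment kind {kind!r}; expected one of {EXPERIMENT_KINDS}")
    frame = _DISPATCH[kind](config, seed)
    name = config.get("name", kind.replace("-", "_"))
    return _write_outputs(Path(out_dir), name, frame, config, seed)
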