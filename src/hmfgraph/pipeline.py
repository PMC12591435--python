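"""End-to-end workflows: data loading, fitting with hyperparameter
selection, network selection, file output, and the benchmark runner."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .edges import (
    NetworkSelection,
    adjacency_at_gamma,
    compute_selection_curves,
    edge_variances,
    select_from_curves,
)
from .metrics import (
    average_clustering_coefficient,
    cluster_labels,
    confusion,
    nmi,
    scores,
)
from .model import Hyperparameters, ModelFit, gem_fit, sample_moments
from .simulate import (
    TrueNetwork,
    generate_cluster,
    generate_scale_free,
    nonparanormal_transform,
    sample_mvn,
)
from .tuning import (
    InfeasibleConditionError,
    heuristic_alpha,
    lw_condition_bound,
    select_alpha_cc,
)

__all__ = ["RunConfig", "load_matrix", "fit_with_alpha", "run_fit_pipeline",
           "run_benchmark", "simulate_dataset"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully validated configuration of one network-recovery run."""

    input_path: str | None = None
    simulate: dict | None = None  # {structure, weights, p, n, seed}
    alpha: float | str = "cc"  # numeric, "cc", or "heuristic"
    beta: float = 0.9
    selection: str = "f1"  # "f1" | "fdr" | "fixed-gamma"
    gamma: float = 0.95  # used only for fixed-gamma selection
    fdr_target: float = 0.2
    K: int | None = None
    n_permutations: int = 50
    seed: int = 0
    standardize: bool = True
    nonparanormal: bool = False
    alpha_tol: float = 0.005
    output_prefix: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path or simulate must be given")
        if isinstance(self.alpha, str) and self.alpha not in ("cc", "heuristic"):
            raise ValueError(f"alpha must be numeric, 'cc' or 'heuristic', got {self.alpha!r}")
        if isinstance(self.alpha, float) and not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"numeric alpha must be in [0, 1), got {self.alpha}")
        if self.selection not in ("f1", "fdr", "fixed-gamma"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        if not 0.0 < self.fdr_target < 1.0:
            raise ValueError("fdr_target must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a delimited samples x variables matrix (CSV/TSV, optional header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    # a header row of variable names is optional: retry headerless if the
    # first row parsed into non-numeric column labels that look like data
    try:
        df = df.apply(pd.to_numeric)
        names = [str(c) for c in df.columns]
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    if all(c.startswith("Unnamed") or _is_number(c) for c in names):
        df = pd.read_csv(path, sep=sep, header=None)
        df = df.apply(pd.to_numeric)
        names = [f"V{i + 1}" for i in range(df.shape[1])]
    Y = df.to_numpy(dtype=float)
    if Y.shape[0] < 3:
        raise ValueError(f"need at least 3 samples, got {Y.shape[0]}")
    if not np.all(np.isfinite(Y)):
        raise ValueError(f"non-finite values in {path}")
    return Y, names


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def simulate_dataset(structure: str, weights: str, p: int, n: int, seed: int
                     ) -> tuple[TrueNetwork, np.ndarray]:
    """Ground-truth network plus one Gaussian dataset drawn from it."""
    if structure in ("scale-free", "scale_free"):
        net = generate_scale_free(p, weights=weights, seed=seed)
    elif structure == "cluster":
        net = generate_cluster(p, weights=weights, seed=seed)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    Y = sample_mvn(net, n, seed=seed + 1_000_003)
    return net, Y


def fit_with_alpha(
    Y: np.ndarray,
    alpha: float | str = "cc",
    beta: float = 0.9,
    standardize: bool = True,
    alpha_tol: float = 0.005,
) -> tuple[ModelFit, dict]:
    """Fit the model, resolving alpha by CC-search, heuristic, or a number."""
    moments = sample_moments(Y, standardize=standardize)
    n, p = moments.n, moments.p
    info: dict = {"beta": beta}
    if alpha == "cc":
        kappa = lw_condition_bound(Y)
        hp = Hyperparameters(alpha=0.5, beta=beta)
        try:
            res = select_alpha_cc(moments, hp, kappa_max=kappa, alpha_tol=alpha_tol)
        except InfeasibleConditionError as exc:
            # very well-conditioned data can undercut the model's best
            # achievable conditioning; fall back to maximal shrinkage
            logger.warning("CC constraint infeasible (%s); using bracket top", exc)
            res = exc.best
        fit = res.fit if res.fit is not None else gem_fit(
            moments, Hyperparameters(alpha=res.alpha_hat, beta=beta))
        info.update(alpha=res.alpha_hat, alpha_mode="cc", kappa_max=kappa,
                    achieved_condition=res.achieved_condition,
                    n_gem_calls=res.n_gem_calls)
    else:
        a = heuristic_alpha(n, p) if alpha == "heuristic" else float(alpha)
        fit = gem_fit(moments, Hyperparameters(alpha=a, beta=beta))
        info.update(alpha=a, alpha_mode="heuristic" if alpha == "heuristic" else "fixed")
    info.update(n_iters=fit.n_iters, converged=fit.converged,
                final_rel_fnorm=fit.final_rel_fnorm)
    return fit, info


def run_fit_pipeline(config: RunConfig) -> dict:
    """Execute the full recovery workflow and (optionally) write outputs.

    read -> (nonparanormal) -> standardize -> alpha selection -> MAP fit ->
    permutation calibration -> interval-width selection -> adjacency +
    reports. Deterministic for a fixed config and seed.
    """
    if config.input_path is not None:
        Y, names = load_matrix(config.input_path)
        net = None
    else:
        sim = dict(config.simulate or {})
        net, Y = simulate_dataset(
            sim.get("structure", "scale-free"), sim.get("weights", "fixed"),
            int(sim.get("p", 100)), int(sim.get("n", 300)),
            int(sim.get("seed", config.seed)),
        )
        names = [f"V{i + 1}" for i in range(Y.shape[1])]
    if config.nonparanormal:
        Y = nonparanormal_transform(Y)

    fit, info = fit_with_alpha(Y, alpha=config.alpha, beta=config.beta,
                               standardize=config.standardize,
                               alpha_tol=config.alpha_tol)

    report: dict = {"config": asdict(config), "config_hash": config.digest(),
                    "fit": info, "n": fit.moments.n, "p": fit.moments.p}
    if config.selection == "fixed-gamma":
        sd = np.sqrt(edge_variances(fit))
        adj = adjacency_at_gamma(fit.omega_hat, sd, config.gamma)
        gamma = config.gamma
        report["selection"] = {"method": "fixed-gamma", "gamma": gamma,
                               "n_edges": int(adj.sum() // 2)}
        sel = None
    else:
        curves = compute_selection_curves(Y, fit, n_perm=config.n_permutations,
                                          seed=config.seed)
        sel = select_from_curves(fit, curves, method=config.selection,
                                 fdr_target=config.fdr_target, K=config.K)
        adj, gamma = sel.adjacency, sel.gamma
        report["selection"] = {
            "method": sel.method, "gamma": sel.gamma,
            "n_edges": int(adj.sum() // 2),
            "estimated_fdr": sel.estimated_fdr,
            "estimated_f1": sel.estimated_f1,
            "n_permutations": curves.n_permutations,
        }

    if net is not None:
        c = confusion(adj, net.adjacency)
        report["truth_metrics"] = scores(c)
        report["truth_metrics"]["acc"] = average_clustering_coefficient(adj)

    if config.output_prefix is not None:
        _write_outputs(config.output_prefix, fit, adj, gamma, names, report)
    report["adjacency"] = adj
    report["omega_hat"] = fit.omega_hat
    return report


def _write_outputs(prefix: str, fit: ModelFit, adj: np.ndarray, gamma: float,
                   names: list[str], report: dict) -> None:
    prefix_path = Path(prefix)
    prefix_path.parent.mkdir(parents=True, exist_ok=True)
    p = adj.shape[0]
    sd = np.sqrt(edge_variances(fit))
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            if adj[i, j]:
                rows.append((names[i], names[j], fit.omega_hat[i, j],
                             abs(fit.omega_hat[i, j]) / sd[i, j]))
    pd.DataFrame(rows, columns=["node_i", "node_j", "omega_hat", "z_score"]).to_csv(
        f"{prefix}_edges.tsv", sep="\t", index=False)
    pd.DataFrame(adj, index=names, columns=names).to_csv(f"{prefix}_adjacency.csv")
    g = nx.from_numpy_array(adj)
    nx.relabel_nodes(g, dict(enumerate(names)), copy=False)
    nx.write_graphml(g, f"{prefix}_network.graphml")
    with open(f"{prefix}_report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if k not in ("adjacency", "omega_hat")}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Benchmark runner
# ---------------------------------------------------------------------------

_ALPHA_MODES = ("cc", "heuristic")
_SELECTORS = ("f1", "fdr")


def run_benchmark(
    grid: list[dict],
    n_perm: int = 50,
    fdr_target: float = 0.2,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Run the simulation-study grid and aggregate recovery metrics.

    Each grid cell is a dict with keys structure, weights, n, p, reps, seed.
    For every replicate both alpha modes (CC and heuristic) and both
    interval selectors (estimated-F1 maximum and FDR target) are scored
    against the true network; the result table reports mean and SD per
    cell, alpha mode and selector.
    """
    records = []
    for cell in grid:
        structure, weights = cell["structure"], cell["weights"]
        n, p, reps = int(cell["n"]), int(cell["p"]), int(cell["reps"])
        base_seed = int(cell.get("seed", 0))
        failures = 0
        for rep in range(reps):
            seed = base_seed + 7919 * rep
            try:
                net, Y = simulate_dataset(structure, weights, p, n, seed)
                for mode in _ALPHA_MODES:
                    fit, info = fit_with_alpha(Y, alpha=mode)
                    curves = compute_selection_curves(Y, fit, n_perm=n_perm, seed=seed)
                    for selector in _SELECTORS:
                        sel = select_from_curves(fit, curves, method=selector,
                                                 fdr_target=fdr_target)
                        records.append(_score_record(
                            cell, rep, mode, selector, info, sel, net))
            except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
                failures += 1
                logger.warning("replicate %d of cell %s failed: %s", rep, cell, exc)
        if failures:
            logger.warning("cell %s completed with %d/%d failed reps",
                           cell, failures, reps)
    raw = pd.DataFrame.from_records(records)
    if raw.empty:
        raise RuntimeError("every benchmark replicate failed; see warnings")
    metric_cols = ["mcc", "f1", "fdr", "tpr", "acc", "nmi", "n_edges", "alpha"]
    agg = raw.groupby(["structure", "weights", "n", "p", "alpha_mode", "selector"])[
        metric_cols].agg(["mean", "std"]).reset_index()
    agg.columns = ["_".join(c).rstrip("_") for c in agg.columns]
    agg["reps_completed"] = raw.groupby(
        ["structure", "weights", "n", "p", "alpha_mode", "selector"]
    ).size().to_numpy()
    if out_csv is not None:
        agg.to_csv(out_csv, index=False)
    return agg


def _score_record(cell, rep, mode, selector, info, sel: NetworkSelection,
                  net: TrueNetwork) -> dict:
    m = scores(confusion(sel.adjacency, net.adjacency))
    rec = dict(structure=cell["structure"], weights=cell["weights"],
               n=int(cell["n"]), p=int(cell["p"]), rep=rep,
               alpha_mode=mode, selector=selector, alpha=info["alpha"],
               gamma=sel.gamma, n_edges=int(sel.adjacency.sum() // 2), **m)
    rec["acc"] = average_clustering_coefficient(sel.adjacency)
    if net.cluster_labels is not None:
        rec["nmi"] = nmi(cluster_labels(sel.adjacency), net.cluster_labels)
    else:
        rec["nmi"] = np.nan
    return rec
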