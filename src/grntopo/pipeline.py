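"""End-to-end orchestration: expression -> network -> balance -> topology,
and directional comparison of two cohorts.

A cohort run executes variance filtering, covariance estimation, graphical
lasso, coupling extraction, the triad census, the clique-complex filtration
and persistence, and condenses the result into a
:class:`CohortTopologyReport`. Two reports built under the same configuration
can be compared with :func:`compare_cohorts`, which emits the directional
flags the two-cohort analysis turns on: which network becomes connected at a
smaller threshold, which carries more essential loops/voids, and which
saturates beta_2 earlier and lower.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .balance import TriadCensus, enumerate_triads, quartic_energy
from .containers import ExpressionMatrix, InteractionNetwork
from .inference import infer_network, select_penalty
from .synthetic import SyntheticCohort
from .topology import (
    BettiCurve,
    PersistencePair,
    betti_curve,
    build_clique_filtration,
    compute_persistence,
    essential_features,
)

__all__ = [
    "PipelineConfig",
    "CohortTopologyReport",
    "ComparisonReport",
    "weight_histogram",
    "run_cohort",
    "run_network",
    "compare_cohorts",
    "write_report",
    "load_pairs_csv",
    "summaries_from_pairs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters of one analysis run.

    ``penalty=None`` selects the graphical-lasso penalty by the held-out
    log-likelihood heuristic and records the chosen value in the report.
    """

    penalty: float | None = None
    top_k: int | None = None
    max_dim: int = 3
    weight_transform: str = "absolute"
    tol: float = 1e-6
    max_iter: int = 500
    use_correlation: bool = False
    bins: int = 30
    seed: int = 0

    def analysis_fields(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("seed")
        return d


def weight_histogram(net: InteractionNetwork, bins: int | np.ndarray = 30) -> dict:
    """Histogram of signed weights of present edges, with spread summaries."""
    w = net.edge_weights()
    if w.size == 0:
        raise ValueError("network has no edges to histogram")
    counts, edges = np.histogram(w, bins=bins)
    absq = np.quantile(np.abs(w), [0.25, 0.5, 0.75])
    return {
        "edges": edges,
        "counts": counts,
        "std": float(w.std()),
        "abs_std": float(np.abs(w).std()),
        "abs_quantiles": {"q25": float(absq[0]), "q50": float(absq[1]), "q75": float(absq[2])},
        "n_edges": int(w.size),
    }


@dataclass
class CohortTopologyReport:
    """Topological and balance summary of one cohort's coupling network."""

    label: str
    config: PipelineConfig
    penalty_used: float
    network: InteractionNetwork
    census: TriadCensus
    pairs: list[PersistencePair]
    curves: BettiCurve
    histogram: dict
    essential_counts: dict[int, int]
    connected: bool
    beta0_connect_threshold: float | None
    beta1_onset_threshold: float | None
    beta2_plateau: tuple[float | None, int]
    quartic: tuple[float, float] = (0.0, 0.0)

    def summary_dict(self) -> dict:
        h, s = self.quartic
        return {
            "label": self.label,
            "config": {**self.config.analysis_fields(), "seed": self.config.seed},
            "penalty_used": self.penalty_used,
            "n_nodes": self.network.n_nodes,
            "n_edges": int(self.network.edge_weights().size),
            "sparsity": self.network.sparsity,
            "weight_std": self.histogram["std"],
            "weight_abs_std": self.histogram["abs_std"],
            "triads": {
                "total": len(self.census.triads),
                "balanced": self.census.n_balanced,
                "imbalanced": self.census.n_imbalanced,
                "counts": dict(self.census.counts),
                "triadic_hamiltonian": self.census.total_balance_energy,
                "quartic_hamiltonian": h,
                "square_count": s,
            },
            "essential_counts": {int(k): int(v) for k, v in self.essential_counts.items()},
            "connected": self.connected,
            "beta0_connect_threshold": self.beta0_connect_threshold,
            "beta1_onset_threshold": self.beta1_onset_threshold,
            "beta2_plateau_threshold": self.beta2_plateau[0],
            "beta2_plateau_value": self.beta2_plateau[1],
            "n_pairs": len(self.pairs),
        }


def summaries_from_pairs(pairs: list[PersistencePair], max_dim: int = 3) -> dict:
    """Threshold summaries derived from persistence pairs alone.

    Everything the comparison needs is recomputable from the persisted pairs:
    essential counts, the connectivity threshold (smallest w with beta_0 = 1,
    defined only when exactly one dimension-0 class is essential), the loop
    onset (smallest dimension-1 birth), and the beta_2 plateau (first
    threshold where beta_2 attains its maximum, with that maximum).
    """
    ess = essential_features(pairs)
    essential_counts = {k: len(v) for k, v in ess.items()}
    connected = essential_counts.get(0, 0) == 1

    curves = betti_curve(pairs, max_dim=max_dim)
    grid, beta = curves.thresholds, curves.beta

    beta0_connect = None
    if connected:
        ones = np.nonzero(beta[0] == 1)[0]
        if ones.size:
            beta0_connect = float(grid[ones[0]])

    dim1_births = [p.birth for p in pairs if p.dimension == 1]
    beta1_onset = min(dim1_births) if dim1_births else None

    beta2_plateau: tuple[float | None, int] = (None, 0)
    if max_dim >= 3 and 2 in beta and beta[2].max() > 0:
        m = int(beta[2].max())
        beta2_plateau = (float(grid[np.nonzero(beta[2] == m)[0][0]]), m)

    return {
        "essential_counts": essential_counts,
        "connected": connected,
        "beta0_connect_threshold": beta0_connect,
        "beta1_onset_threshold": beta1_onset,
        "beta2_plateau": beta2_plateau,
        "curves": curves,
    }


def run_network(
    net: InteractionNetwork,
    config: PipelineConfig = PipelineConfig(),
    label: str = "network",
    penalty_used: float = float("nan"),
) -> CohortTopologyReport:
    """Balance census + persistence + summaries for an existing network."""
    t0 = time.perf_counter()
    census = enumerate_triads(net)
    quartic = quartic_energy(net, census=census)
    filt = build_clique_filtration(
        net, max_dim=config.max_dim, weight_transform=config.weight_transform
    )
    pairs = compute_persistence(filt, validate=False)
    summ = summaries_from_pairs(pairs, max_dim=config.max_dim)
    if net.edge_weights().size:
        hist = weight_histogram(net, bins=config.bins)
    else:  # edgeless (null-model) network: empty histogram descriptor
        hist = {
            "edges": np.array([0.0, 1.0]), "counts": np.array([0]),
            "std": 0.0, "abs_std": 0.0,
            "abs_quantiles": {"q25": 0.0, "q50": 0.0, "q75": 0.0},
            "n_edges": 0,
        }
    logger.info(
        "topology for %s: %d nodes, %d simplices, %d pairs (%.2fs)",
        label, net.n_nodes, len(filt), len(pairs), time.perf_counter() - t0,
    )
    return CohortTopologyReport(
        label=label,
        config=config,
        penalty_used=penalty_used,
        network=net,
        census=census,
        pairs=pairs,
        curves=summ["curves"],
        histogram=hist,
        essential_counts=summ["essential_counts"],
        connected=summ["connected"],
        beta0_connect_threshold=summ["beta0_connect_threshold"],
        beta1_onset_threshold=summ["beta1_onset_threshold"],
        beta2_plateau=summ["beta2_plateau"],
        quartic=quartic,
    )


def run_cohort(
    data: ExpressionMatrix | SyntheticCohort,
    config: PipelineConfig = PipelineConfig(),
    label: str | None = None,
) -> CohortTopologyReport:
    """Full pipeline for one cohort: inference then balance and topology."""
    if isinstance(data, SyntheticCohort):
        expr = data.expression
        label = label or data.label
    else:
        expr = data
        label = label or "cohort"
    penalty = config.penalty
    if penalty is None:
        penalty = select_penalty(expr, seed=config.seed, tol=config.tol,
                                 max_iter=config.max_iter)
        logger.info("selected penalty %.4g for %s", penalty, label)
    net = infer_network(
        expr,
        penalty=penalty,
        top_k=config.top_k,
        tol=config.tol,
        max_iter=config.max_iter,
        use_correlation=config.use_correlation,
    )
    return run_network(net, config=config, label=label, penalty_used=penalty)


@dataclass
class ComparisonReport:
    """Deltas and directional flags between two cohort reports."""

    report_a: CohortTopologyReport
    report_b: CohortTopologyReport
    deltas: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label_a": self.report_a.label,
            "label_b": self.report_b.label,
            "deltas": self.deltas,
            "flags": self.flags,
        }


def _delta(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return a - b


def _earlier(a: float | None, b: float | None) -> str:
    if a is None and b is None:
        return "tie"
    if a is None:
        return "b"
    if b is None:
        return "a"
    return "a" if a < b else ("b" if b < a else "tie")


def compare_cohorts(
    report_a: CohortTopologyReport, report_b: CohortTopologyReport
) -> ComparisonReport:
    """Compare two cohort reports built under identical analysis settings.

    Seeds may differ (they only steer penalty selection splits); every other
    configuration field must match.
    """
    if report_a.config.analysis_fields() != report_b.config.analysis_fields():
        raise ValueError("cohort reports were built with different configurations")

    sa, sb = report_a.summary_dict(), report_b.summary_dict()
    keys = [
        "weight_std",
        "weight_abs_std",
        "sparsity",
        "beta0_connect_threshold",
        "beta1_onset_threshold",
        "beta2_plateau_threshold",
        "beta2_plateau_value",
    ]
    deltas = {k: _delta(sa[k], sb[k]) for k in keys}
    ea = report_a.essential_counts
    eb = report_b.essential_counts
    deltas["essential_loops"] = ea.get(1, 0) - eb.get(1, 0)
    deltas["essential_voids"] = ea.get(2, 0) - eb.get(2, 0)

    flags = {
        "connects_earlier": _earlier(
            sa["beta0_connect_threshold"], sb["beta0_connect_threshold"]
        ),
        "loops_onset_earlier": _earlier(
            sa["beta1_onset_threshold"], sb["beta1_onset_threshold"]
        ),
        "more_essential_loops": (
            "a" if deltas["essential_loops"] > 0
            else ("b" if deltas["essential_loops"] < 0 else "tie")
        ),
        "more_essential_voids": (
            "a" if deltas["essential_voids"] > 0
            else ("b" if deltas["essential_voids"] < 0 else "tie")
        ),
        "beta2_saturates_earlier": _earlier(
            sa["beta2_plateau_threshold"], sb["beta2_plateau_threshold"]
        ),
        "beta2_saturates_lower": (
            "a" if sa["beta2_plateau_value"] < sb["beta2_plateau_value"]
            else ("b" if sb["beta2_plateau_value"] < sa["beta2_plateau_value"] else "tie")
        ),
    }
    return ComparisonReport(report_a=report_a, report_b=report_b, deltas=deltas, flags=flags)


# ---------------------------------------------------------------------------
# Persistence of reports to text files
# ---------------------------------------------------------------------------


def write_report(report: CohortTopologyReport, out_dir: str | Path) -> dict[str, Path]:
    """Write network, pairs, curves, summary and resolved config as text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["network"] = out / f"{report.label}_network.tsv"
    report.network.to_edgelist_tsv(paths["network"])

    paths["pairs"] = out / f"{report.label}_persistence_pairs.csv"
    with open(paths["pairs"], "w") as fh:
        fh.write("dimension,birth,death\n")
        for p in report.pairs:
            death = "inf" if p.essential else f"{p.death:.17g}"
            fh.write(f"{p.dimension},{p.birth:.17g},{death}\n")

    paths["betti"] = out / f"{report.label}_betti_curves.csv"
    with open(paths["betti"], "w") as fh:
        dims = sorted(report.curves.beta)
        fh.write("threshold," + ",".join(f"b{k}" for k in dims) + "\n")
        for i, w in enumerate(report.curves.thresholds):
            row = ",".join(str(int(report.curves.beta[k][i])) for k in dims)
            fh.write(f"{w:.17g},{row}\n")

    paths["summary"] = out / f"{report.label}_summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, default=float)
        fh.write("\n")
    return paths


def load_pairs_csv(path: str | Path) -> list[PersistencePair]:
    """Read back a persistence-pairs CSV written by :func:`write_report`."""
    df = pd.read_csv(path, float_precision="round_trip")
    pairs = []
    for _, row in df.iterrows():
        death = math.inf if str(row["death"]) in ("inf", "Infinity") else float(row["death"])
        pairs.append(PersistencePair(int(row["dimension"]), float(row["birth"]), death))
    return pairs
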