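"""Tandem-fluorescent reporter flux statistics from per-event flow data.

A tandem RFP-GFP fusion (to LC3 or an autophagy receptor) reports
autophagic flux as the per-cell Red:Green ratio: GFP is quenched in the
acidic lysosome while RFP persists, so flux raises the ratio. This module
computes per-event ratios, quantile summaries (median, inner quartiles,
10th/90th percentiles), normalization of a summary to a reference
population's median (e.g. the BafA1-treated minimal-flux state), unbiased
bimodal deconvolution of knockout populations, and the fold-repression
score

    (ratio_sgGene - ratio_sgATG9A) / (ratio_sgControl - ratio_sgATG9A)

which maps a knockout's median ratio onto [0, 1] under the assumption that
the ATG9A knockout is a true autophagy null (0 = no repression relative to
the null, 1 = control-like flux; out-of-range values are reported as-is
and flagged).

The bimodal gate is a deterministic replacement for interactive bifurcation
gating: the threshold on log10 ratio minimizes the within-class variance
over a 256-bin histogram by exhaustive scan (Otsu's criterion), requiring
no user threshold. Populations whose between-class variance fraction falls
below a floor are flagged degenerate (effectively unimodal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptyPopulationError,
    InsufficientEventsError,
    InvalidParameterError,
    UndefinedScoreError,
)

DEFAULT_MIN_EVENTS = 1000  # summary-statistics floor (n > 1,000 cells per sample)
DEFAULT_BIFURCATION_BINS = 256
DEFAULT_DEGENERATE_FLOOR = 0.75  # between/total variance fraction below which the gate is degenerate


@dataclass
class FlowPopulation:
    """Per-event intensities plus sample metadata."""

    events: pd.DataFrame  # columns RFP, GFP
    reporter: str = ""
    genotype: str = ""
    treatment: str = "basal"

    def __post_init__(self) -> None:
        missing = {"RFP", "GFP"} - set(self.events.columns)
        if missing:
            raise InvalidParameterError(f"event table lacks columns {sorted(missing)}")


def compute_ratios(pop: FlowPopulation) -> tuple[np.ndarray, int]:
    """Per-event RFP/GFP ratios; events with GFP <= 0 excluded and tallied.

    Returns ``(ratios, n_excluded)``.
    """
    rfp = pop.events["RFP"].to_numpy(dtype=float)
    gfp = pop.events["GFP"].to_numpy(dtype=float)
    ok = gfp > 0
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise EmptyPopulationError("all events excluded (GFP <= 0); no ratios")
    return rfp[ok] / gfp[ok], n_excluded


@dataclass
class FluxSummary:
    """Quantile summary of a ratio distribution.

    Invariant: p10 <= q25 <= median <= q75 <= p90.
    """

    median: float
    q25: float
    q75: float
    p10: float
    p90: float
    n: int
    reference: str = "none"

    def as_dict(self) -> dict:
        return dict(median=self.median, q25=self.q25, q75=self.q75,
                    p10=self.p10, p90=self.p90, n=self.n, reference=self.reference)


def summarize(ratios: np.ndarray, min_events: int = DEFAULT_MIN_EVENTS) -> FluxSummary:
    """Median, inner quartiles, and 10th/90th percentiles (linear interpolation)."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < min_events:
        raise InsufficientEventsError(
            f"{ratios.size} events < configured minimum {min_events}"
        )
    p10, q25, med, q75, p90 = np.percentile(ratios, [10, 25, 50, 75, 90])
    return FluxSummary(median=float(med), q25=float(q25), q75=float(q75),
                       p10=float(p10), p90=float(p90), n=int(ratios.size))


def normalize(summary: FluxSummary, reference: FluxSummary, label: str = "reference") -> FluxSummary:
    """Divide every quantile by the reference population's median (order-preserving)."""
    if reference.median <= 0:
        raise InvalidParameterError("reference median must be > 0")
    m = reference.median
    return FluxSummary(
        median=summary.median / m, q25=summary.q25 / m, q75=summary.q75 / m,
        p10=summary.p10 / m, p90=summary.p90 / m, n=summary.n, reference=label,
    )


# ---------------------------------------------------------------------------
# Bimodal deconvolution


@dataclass
class BifurcationGate:
    """Threshold splitting a (log-)bimodal ratio population.

    ``threshold`` is on the ratio scale; fractions/medians describe the
    low and high subpopulations. ``separation`` is the between-class
    variance as a fraction of total log-ratio variance at the optimum;
    ``degenerate`` flags populations where it falls below the floor.
    """

    threshold: float
    low_fraction: float
    high_fraction: float
    low_median: float
    high_median: float
    separation: float
    degenerate: bool


def _otsu_scan(log_ratios: np.ndarray, bins: int):
    """Exhaustive two-class variance scan over histogram bin boundaries.

    Returns (best threshold in log units, between-class variance at the
    optimum, total variance).
    """
    hist, edges = np.histogram(log_ratios, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    if total == 0:
        raise EmptyPopulationError("no events to gate")
    p = w / total
    omega0 = np.cumsum(p)[:-1]  # class-0 weight up to each boundary
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    mu0 = np.divide(mu_cum[:-1], omega0, out=np.zeros(bins - 1), where=omega0 > 0)
    omega1 = 1.0 - omega0
    mu1 = np.divide(mu_total - mu_cum[:-1], omega1, out=np.zeros(bins - 1), where=omega1 > 0)
    between = omega0 * omega1 * (mu0 - mu1) ** 2
    valid = (omega0 > 0) & (omega1 > 0)
    between[~valid] = -np.inf
    k = int(np.argmax(between))
    # with well-separated modes every boundary across the empty valley is
    # exactly optimal; take the middle of the tied plateau around the optimum
    tol = 1e-12 * max(1.0, abs(between[k]))
    lo = hi = k
    while lo - 1 >= 0 and between[lo - 1] >= between[k] - tol:
        lo -= 1
    while hi + 1 < between.size and between[hi + 1] >= between[k] - tol:
        hi += 1
    k = (lo + hi) // 2
    total_var = float(((centers - mu_total) ** 2 * p).sum())
    return float(edges[k + 1]), float(between[k]), total_var


def bifurcate(
    ratios: np.ndarray,
    bins: int = DEFAULT_BIFURCATION_BINS,
    min_events: int = DEFAULT_MIN_EVENTS,
    degenerate_floor: float = DEFAULT_DEGENERATE_FLOOR,
) -> BifurcationGate:
    """Unbiased bimodal gate on log10 ratio by two-class variance minimization."""
    ratios = np.asarray(ratios, dtype=float)
    ratios = ratios[ratios > 0]
    if ratios.size < min_events:
        raise InsufficientEventsError(f"{ratios.size} events < minimum {min_events}")
    logr = np.log10(ratios)
    thr_log, between, total_var = _otsu_scan(logr, bins)
    low = ratios[logr <= thr_log]
    high = ratios[logr > thr_log]
    separation = between / total_var if total_var > 0 else 0.0
    return BifurcationGate(
        threshold=float(10.0 ** thr_log),
        low_fraction=len(low) / ratios.size,
        high_fraction=len(high) / ratios.size,
        low_median=float(np.median(low)) if len(low) else float("nan"),
        high_median=float(np.median(high)) if len(high) else float("nan"),
        separation=float(separation),
        degenerate=bool(separation < degenerate_floor),
    )


# ---------------------------------------------------------------------------
# Fold repression


def fold_repression(median_gene: float, median_atg9a: float, median_control: float):
    """(gene - ATG9A) / (control - ATG9A); no clamping.

    Returns ``(score, flagged)`` where ``flagged`` is True when the score
    falls outside [0, 1] (reported as-is). Raises when the control and
    ATG9A medians coincide (undefined denominator).
    """
    denom = median_control - median_atg9a
    if denom == 0:
        raise UndefinedScoreError("control and ATG9A medians coincide; fold repression undefined")
    score = (median_gene - median_atg9a) / denom
    return score, bool(score < 0.0 or score > 1.0)


def fold_repression_matrix(
    medians: pd.DataFrame, atg9a_gene: str = "ATG9A", control_gene: str = "control"
) -> pd.DataFrame:
    """Gene x reporter fold-repression matrix (heat-map table layout).

    ``medians`` is gene x reporter of median Red:Green ratios and must
    contain rows for the ATG9A and control references.
    """
    for row in (atg9a_gene, control_gene):
        if row not in medians.index:
            raise InvalidParameterError(f"medians table lacks required row {row!r}")
    out = {}
    for col in medians.columns:
        a = medians.at[atg9a_gene, col]
        c = medians.at[control_gene, col]
        out[col] = {
            g: fold_repression(medians.at[g, col], a, c)[0] for g in medians.index
        }
    mat = pd.DataFrame(out)
    mat.index.name = "gene"
    return mat


# ---------------------------------------------------------------------------
# I/O


def read_events_csv(path) -> pd.DataFrame:
    """Per-event CSV with at least RFP and GFP columns (sample_id optional)."""
    df = pd.read_csv(path)
    if not {"RFP", "GFP"}.issubset(df.columns):
        raise InvalidParameterError("event CSV must have RFP and GFP columns")
    return df


def write_summary_csv(path, summaries: dict[str, FluxSummary]) -> None:
    rows = [dict(sample=k, **s.as_dict()) for k, s in summaries.items()]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


__all__ = [
    "DEFAULT_MIN_EVENTS", "FlowPopulation", "FluxSummary", "BifurcationGate",
    "compute_ratios", "summarize", "normalize", "bifurcate",
    "fold_repression", "fold_repression_matrix",
    "read_events_csv", "write_summary_csv",
]
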