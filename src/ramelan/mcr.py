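"""Multivariate Curve Resolution - Alternating Least Squares (MCR-ALS).

Decomposes a spectra matrix D (n_spectra x n_channels) into non-negative
scores C (n x k) and loadings S (k x p) with D ~ C @ S. Each half-step is
an exact (non-negative) least-squares solve, so the lack of fit

    lof% = 100 * sqrt(sum(residual^2) / sum(D^2))

is non-increasing across iterations. After every loadings update the rows
of S are renormalized to unit Euclidean norm and the columns of C rescaled
to compensate, leaving C @ S unchanged: scores then carry the (relative)
concentration scale and loadings are comparable spectra.

Component-to-pigment assignment uses integrated band windows: the DHICA
subunit of eumelanin is recognized by its sharp carboxylic-acid band at
1787 cm^-1, whole eumelanin by its two broad bands at 1310 and 1595 cm^-1,
and the glass substrate by its very broad band around 1378 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import WavenumberAxis
from .errors import AssignmentError, ConfigurationError, ConsistencyError, FitError

# Band windows (cm^-1) used for pigment assignment, with the minimum
# fraction of a loading's total integrated intensity that must fall inside
# the window for the label to qualify.
DHICA_WINDOW = (1787.0 - 15.0, 1787.0 + 15.0)
EUMELANIN_WINDOWS = ((1310.0 - 40.0, 1310.0 + 40.0), (1595.0 - 40.0, 1595.0 + 40.0))
GLASS_WINDOW = (1378.0 - 80.0, 1378.0 + 80.0)
_DHICA_MIN_FRACTION = 0.10
_EUMELANIN_MIN_FRACTION = 0.05
_GLASS_MIN_FRACTION = 0.15


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors (0 if either is zero)."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class MCRConfig:
    """Settings for one MCR-ALS fit.

    ``tol_lof`` is the absolute change in lack-of-fit (percentage points)
    below which iteration stops; non-negativity on scores and loadings is
    on by default because pigment abundances and Raman intensities are
    physical quantities.
    """

    n_components: int = 3
    init: str = "purest_variable"  # purest_variable | random | provided
    nonneg_scores: bool = True
    nonneg_loadings: bool = True
    max_iter: int = 500
    tol_lof: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if self.max_iter < 1 or self.tol_lof <= 0:
            raise ConfigurationError("max_iter >= 1 and tol_lof > 0 required")
        if self.init not in ("purest_variable", "random", "provided"):
            raise ConfigurationError(f"unknown init mode {self.init!r}")


@dataclass
class MCRResult:
    """Fitted decomposition: unit-norm loadings (k x p), scores (n x k)."""

    loadings: np.ndarray
    scores: np.ndarray
    lof_percent: float
    explained_variance_percent: float
    n_iter: int
    converged: bool
    lof_history: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.scores @ self.loadings


def _solve_ls(basis: np.ndarray, targets: np.ndarray, nonneg: bool) -> np.ndarray:
    """Solve min ||basis @ X - targets||_F column-wise, optionally X >= 0.

    basis is m x k (k small). Uses the reduced QR so each non-negative
    column solve is a k x k problem; columns whose unconstrained solution
    is already feasible skip the active-set solver.
    """
    q, r = np.linalg.qr(basis)
    rhs = q.T @ targets
    if not nonneg:
        return np.linalg.lstsq(basis, targets, rcond=None)[0]
    try:
        x = np.linalg.solve(r, rhs)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(r, rhs, rcond=None)[0]
    bad = np.where((x < -1e-12).any(axis=0))[0]
    x = np.clip(x, 0.0, None)
    for j in bad:
        x[:, j] = nnls(r, rhs[:, j])[0]
    return x


def initialize_loadings(
    data: np.ndarray,
    config: MCRConfig,
    provided: np.ndarray | None = None,
) -> np.ndarray:
    """Initial loadings (k x p, unit-norm rows) for the ALS iteration.

    ``purest_variable`` is a SIMPLISMA-style selection of the k purest
    channels (highest std/mean purity on a lightly smoothed copy of the
    data, channels below 5% of the maximum mean excluded as noise-
    dominated, successive picks down-weighted by correlation with already
    selected channels, lowest-index tie-break); the selected columns act
    as initial concentration profiles and one constrained least-squares
    step turns them into loadings. ``random`` draws seeded non-negative
    vectors. ``provided`` validates and renormalizes user loadings.
    """
    data = np.asarray(data, dtype=float)
    n, p = data.shape
    k = config.n_components
    if k > min(n, p):
        raise ConfigurationError(
            f"k={k} exceeds min(n_spectra, n_channels)={min(n, p)}"
        )
    if config.init == "provided":
        if provided is None:
            raise ConfigurationError("init='provided' needs loadings")
        loadings = np.asarray(provided, dtype=float)
        if loadings.shape != (k, p):
            raise ConfigurationError(f"provided loadings must be {k} x {p}")
        if config.nonneg_loadings and np.any(loadings < 0):
            raise ConfigurationError("provided loadings violate non-negativity")
        norms = np.linalg.norm(loadings, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ConfigurationError("provided loadings contain a zero row")
        return loadings / norms
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        loadings = rng.uniform(0.1, 1.0, size=(k, p))
        return loadings / np.linalg.norm(loadings, axis=1, keepdims=True)

    # purest_variable: SIMPLISMA-style purity over channels (columns)
    if p >= 9:
        from scipy.signal import savgol_filter

        smoothed = savgol_filter(data, 9, 3, axis=1)
    else:
        smoothed = data
    means = smoothed.mean(axis=0)
    stds = smoothed.std(axis=0)
    alpha = 0.05 * max(means.max(), 1e-300)
    purity = stds / (means + alpha)
    purity[means < 0.05 * means.max()] = 0.0  # noise-dominated channels
    col_norms = np.linalg.norm(smoothed, axis=0)
    unit = np.divide(
        smoothed, col_norms, out=np.zeros_like(smoothed), where=col_norms > 0
    )
    chosen: list[int] = []
    weights = np.ones(p)
    for _ in range(k):
        score = purity * weights
        score[chosen] = -np.inf
        idx = int(np.argmax(score))  # argmax takes the lowest index on ties
        chosen.append(idx)
        overlap = np.abs(unit.T @ unit[:, idx])
        weights = weights * np.clip(1.0 - overlap**2, 0.0, None)
    concentrations = data[:, chosen]
    loadings = _solve_ls(concentrations, data, config.nonneg_loadings)
    if not config.nonneg_loadings:
        loadings = np.asarray(loadings)
    row_norms = np.linalg.norm(loadings, axis=1, keepdims=True)
    if np.any(row_norms == 0):
        raise FitError("purest-variable initialization produced a zero loading")
    return loadings / row_norms


def fit_mcr_als(
    data: np.ndarray,
    config: MCRConfig,
    initial_loadings: np.ndarray | None = None,
) -> MCRResult:
    """Run the alternating least-squares iteration to convergence."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ConfigurationError("data must be a 2-D matrix")
    if not np.all(np.isfinite(data)):
        raise FitError("data contains non-finite values")
    loadings = initialize_loadings(data, config, provided=initial_loadings)
    total_ss = float(np.sum(data**2))
    if total_ss == 0:
        raise FitError("data matrix is identically zero")

    lof_history: list[float] = []
    prev_lof = np.inf
    converged = False
    n_iter = 0
    scores = np.zeros((data.shape[0], config.n_components))
    for n_iter in range(1, config.max_iter + 1):
        # scores given loadings: rows of D regressed on rows of S
        scores = _solve_ls(loadings.T, data.T, config.nonneg_scores).T
        # loadings given scores
        loadings = _solve_ls(scores, data, config.nonneg_loadings)
        if not (np.all(np.isfinite(scores)) and np.all(np.isfinite(loadings))):
            raise FitError(f"non-finite values at ALS iteration {n_iter}")
        # renormalize: unit-norm loading rows, compensate in scores
        norms = np.linalg.norm(loadings, axis=1)
        norms[norms == 0] = 1.0
        loadings = loadings / norms[:, None]
        scores = scores * norms[None, :]
        residual_ss = float(np.sum((data - scores @ loadings) ** 2))
        lof = 100.0 * np.sqrt(residual_ss / total_ss)
        lof_history.append(lof)
        if abs(prev_lof - lof) < config.tol_lof:
            converged = True
            break
        prev_lof = lof
    residual_ss = float(np.sum((data - scores @ loadings) ** 2))
    return MCRResult(
        loadings=loadings,
        scores=scores,
        lof_percent=100.0 * float(np.sqrt(residual_ss / total_ss)),
        explained_variance_percent=100.0 * (1.0 - residual_ss / total_ss),
        n_iter=n_iter,
        converged=converged,
        lof_history=lof_history,
    )


@dataclass(frozen=True)
class ComponentAssignment:
    """Component index -> pigment label mapping with the band diagnostics."""

    labels: tuple[str, ...]
    diagnostics: pd.DataFrame

    def index_of(self, label: str) -> int:
        if label not in self.labels:
            raise AssignmentError(f"no component assigned to {label!r}")
        return self.labels.index(label)

    def __contains__(self, label: str) -> bool:
        return label in self.labels


def _window_integral(axis: WavenumberAxis, loading: np.ndarray, lo, hi) -> float:
    mask = axis.window(lo, hi)
    return float(np.trapezoid(loading[mask], axis.values[mask])) if mask.sum() > 1 else 0.0


def assign_components(result: MCRResult, axis: WavenumberAxis) -> ComponentAssignment:
    """Label fitted components as dhica / eumelanin / glass / unassigned.

    Selection is greedy with deterministic lowest-index tie-breaks:
    DHICA first (largest 1787 cm^-1 window integral weighted by its
    sharpness, i.e. that integral over the total), then whole eumelanin
    (largest min of the 1310/1595 window integrals), then glass (largest
    1378 +/- 80 integral outside the eumelanin windows). A component must
    hold a minimum fraction of its intensity in the defining window to
    qualify, so spurious components stay unassigned.
    """
    if axis.values[0] > 1250.0 or axis.values[-1] < 1850.0 - 1e-9:
        raise AssignmentError(
            "axis must cover 1250-1850 cm^-1 for pigment assignment"
        )
    k = result.n_components
    rows = []
    for i in range(k):
        loading = np.abs(result.loadings[i])
        total = float(np.trapezoid(loading, axis.values))
        total = max(total, 1e-300)
        i_dhica = _window_integral(axis, loading, *DHICA_WINDOW)
        i_1310 = _window_integral(axis, loading, *EUMELANIN_WINDOWS[0])
        i_1595 = _window_integral(axis, loading, *EUMELANIN_WINDOWS[1])
        glass_lo, glass_hi = GLASS_WINDOW
        i_glass = _window_integral(axis, loading, glass_lo, glass_hi)
        for lo, hi in EUMELANIN_WINDOWS:
            i_glass -= _window_integral(
                axis, loading, max(lo, glass_lo), min(hi, glass_hi)
            )
        rows.append(
            {
                "component": i,
                "total": total,
                "dhica_integral": i_dhica,
                "dhica_fraction": i_dhica / total,
                "eumelanin_integral": min(i_1310, i_1595),
                "eumelanin_fraction": min(i_1310, i_1595) / total,
                "glass_integral": i_glass,
                "glass_fraction": i_glass / total,
            }
        )
    diag = pd.DataFrame(rows)
    labels = ["unassigned"] * k
    remaining = list(range(k))

    def pick(metric: np.ndarray, fraction: np.ndarray, min_fraction: float):
        best, best_val = None, -np.inf
        for i in remaining:
            if fraction[i] >= min_fraction and metric[i] > best_val:
                best, best_val = i, metric[i]
        return best

    dhica_metric = (diag["dhica_integral"] * diag["dhica_fraction"]).to_numpy()
    i = pick(dhica_metric, diag["dhica_fraction"].to_numpy(), _DHICA_MIN_FRACTION)
    if i is not None:
        labels[i] = "dhica"
        remaining.remove(i)
    i = pick(
        diag["eumelanin_integral"].to_numpy(),
        diag["eumelanin_fraction"].to_numpy(),
        _EUMELANIN_MIN_FRACTION,
    )
    if i is not None:
        labels[i] = "eumelanin"
        remaining.remove(i)
    i = pick(
        diag["glass_integral"].to_numpy(),
        diag["glass_fraction"].to_numpy(),
        _GLASS_MIN_FRACTION,
    )
    if i is not None:
        labels[i] = "glass"
        remaining.remove(i)
    return ComponentAssignment(labels=tuple(labels), diagnostics=diag)


def component_scores_table(
    result: MCRResult,
    assignment: ComponentAssignment,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Tidy per-spectrum pigment-score table joined to metadata."""
    for label in ("dhica", "eumelanin"):
        if label not in assignment:
            raise AssignmentError(f"assignment lacks a {label!r} component")
    if len(meta) != result.scores.shape[0]:
        raise ConsistencyError(
            f"{result.scores.shape[0]} score rows but {len(meta)} metadata rows"
        )
    sample_ids = meta["sample_id"]
    if sample_ids.isna().any() or (sample_ids.astype(str) == "").any():
        raise ConsistencyError("every spectrum needs a sample_id")
    table = meta[["spectrum_id", "sample_id", "class_label"]].copy()
    table["dhica_score"] = result.scores[:, assignment.index_of("dhica")]
    table["eumelanin_score"] = result.scores[:, assignment.index_of("eumelanin")]
    return table.reset_index(drop=True)


def match_components(
    loadings: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian maximum-cosine matching of fitted to reference loadings.

    Returns (permutation, cosines): fitted component permutation[j]
    corresponds to reference row j. Used to score recovery in tests.
    """
    from scipy.optimize import linear_sum_assignment

    k_ref = reference.shape[0]
    cos = np.zeros((k_ref, loadings.shape[0]))
    for a in range(k_ref):
        for b in range(loadings.shape[0]):
            cos[a, b] = cosine_similarity(reference[a], loadings[b])
    rows, cols = linear_sum_assignment(-cos)
    order = cols[np.argsort(rows)]
    return order, cos[np.arange(k_ref), order]
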