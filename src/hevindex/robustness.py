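"""Statistical robustness suite for indicator blocks.

Implements the data-driven checks used to appraise a composite indicator's
construction from a facility x indicator score matrix:

* reliability — Cronbach's alpha, corrected item-total correlations and
  alpha-if-deleted;
* sampling adequacy — Kaiser-Meyer-Olkin (overall and per variable) and
  Bartlett's test of sphericity;
* dimensionality — PCA of the Pearson correlation matrix with the
  eigenvalue-greater-than-1 or cumulative-variance retention rules,
  followed by direct oblimin (oblique) rotation with Kaiser normalization,
  yielding pattern and structure matrices and the component correlation
  matrix;
* reduction advice — items whose absolute pattern loadings fall below a
  threshold (default |0.4|) on the leading components.

All computations operate on the correlation matrix: indicator scales
differ, and the eigenvalue > 1 retention rule presumes unit-variance input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .scoring import DomainError

__all__ = [
    "ItemMatrix",
    "RobustnessReport",
    "pearson_matrix",
    "cronbach_alpha",
    "item_total",
    "kmo",
    "bartlett",
    "pca",
    "oblimin_rotate",
    "drop_suggestions",
    "analyze_block",
]


class SingularMatrixError(ValueError):
    """The correlation matrix is singular; remove collinear/constant items."""


@dataclass(frozen=True)
class ItemMatrix:
    """A facilities x items score matrix for one indicator block."""

    values: np.ndarray
    items: tuple[str, ...]

    def __post_init__(self):
        x = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", x)
        if x.ndim != 2:
            raise DomainError("item matrix must be 2-dimensional")
        if x.shape[1] != len(self.items):
            raise DomainError("item label count must match column count")
        if not np.all(np.isfinite(x)):
            raise DomainError("item matrix must be finite (no missing entries)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def select(self, items: Sequence[str]) -> "ItemMatrix":
        idx = [self.items.index(i) for i in items]
        return ItemMatrix(self.values[:, idx], tuple(items))


def _as_matrix(items) -> ItemMatrix:
    if isinstance(items, ItemMatrix):
        return items
    x = np.asarray(items, dtype=float)
    return ItemMatrix(x, tuple(f"item{i + 1}" for i in range(x.shape[1])))


def pearson_matrix(items: ItemMatrix | np.ndarray, drop_constant: bool = True):
    """Pearson correlation matrix of an item matrix.

    Zero-variance columns carry no correlation information; with
    ``drop_constant`` they are removed (the dropped labels are returned),
    otherwise they raise.
    """
    m = _as_matrix(items)
    if m.n < 3:
        raise DomainError(f"need at least 3 rows for correlations, got {m.n}")
    if m.k < 2:
        raise DomainError("need at least 2 columns")
    variances = m.values.var(axis=0, ddof=1)
    constant = [m.items[i] for i in range(m.k) if variances[i] <= 0]
    if constant and not drop_constant:
        raise DomainError(f"zero-variance item(s): {constant}")
    keep = [i for i in range(m.k) if variances[i] > 0]
    if len(keep) < 2:
        raise DomainError("fewer than 2 items with nonzero variance")
    corr = np.corrcoef(m.values[:, keep], rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr, tuple(m.items[i] for i in keep), tuple(constant)


def cronbach_alpha(items: ItemMatrix | np.ndarray) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(item variances)/var(total))``.

    Ranges over (-inf, 1]; values above 0.7 are conventionally read as
    good internal consistency.
    """
    m = _as_matrix(items)
    if m.k < 2:
        raise DomainError("Cronbach's alpha needs at least 2 items")
    item_var = m.values.var(axis=0, ddof=1)
    total_var = m.values.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DomainError("total-score variance is zero")
    return float(m.k / (m.k - 1) * (1.0 - item_var.sum() / total_var))


def item_total(
    items: ItemMatrix | np.ndarray,
    flag_threshold: float = 0.3,
    severe_threshold: float = 0.2,
) -> dict[str, dict[str, float | bool]]:
    """Corrected item-total correlations and alpha-if-deleted per item.

    Each item is correlated with the *sum of the remaining items*; items
    below ``flag_threshold`` (default 0.3) are flagged as undesirable,
    below ``severe_threshold`` (0.2) as severe.
    """
    m = _as_matrix(items)
    if m.k < 3:
        raise DomainError("item-total analysis needs at least 3 items")
    overall = cronbach_alpha(m)
    out: dict[str, dict[str, float | bool]] = {}
    for i, label in enumerate(m.items):
        rest = np.delete(m.values, i, axis=1)
        rest_total = rest.sum(axis=1)
        col = m.values[:, i]
        if col.std(ddof=1) <= 0 or rest_total.std(ddof=1) <= 0:
            r = 0.0
        else:
            r = float(np.corrcoef(col, rest_total)[0, 1])
        out[label] = {
            "item_total": r,
            "alpha_if_deleted": cronbach_alpha(rest),
            "flagged": r < flag_threshold,
            "severe": r < severe_threshold,
            "overall_alpha": overall,
        }
    return out


def kmo(corr: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy, overall and per variable.

    Compares squared correlations against squared partial correlations
    obtained from the scaled inverse of the correlation matrix::

        KMO = sum r_ij^2 / (sum r_ij^2 + sum a_ij^2)     (i != j)

    where ``a`` is the anti-image (partial) correlation matrix.
    """
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    if r.ndim != 2 or r.shape[0] != r.shape[1] or p < 2:
        raise DomainError("correlation matrix must be square with p >= 2")
    try:
        inv = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        raise SingularMatrixError(
            "correlation matrix is singular; remove collinear or constant items"
        ) from None
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(p, dtype=bool)
    r2 = (r**2)[off].reshape(p, p - 1)
    a2 = (partial**2)[off].reshape(p, p - 1)
    per_variable = r2.sum(axis=1) / (r2.sum(axis=1) + a2.sum(axis=1))
    overall = float(r2.sum() / (r2.sum() + a2.sum()))
    return overall, per_variable


def bartlett(corr: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity (is the correlation matrix identity?).

    Returns ``(chi_square, df, p_value)`` with
    ``chi2 = -(n - 1 - (2p + 5)/6) * ln det(R)`` and ``df = p(p-1)/2``.
    """
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    if n <= p:
        raise DomainError(f"sample size n={n} must exceed number of variables p={p}")
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise DomainError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray
    loadings: np.ndarray          # unrotated, eigenvector * sqrt(eigenvalue)
    explained: np.ndarray         # % of total variance per component
    cumulative: np.ndarray        # cumulative %
    n_components: int
    rule: str
    communalities: np.ndarray     # for the retained components
    items: tuple[str, ...]


def pca(
    items: ItemMatrix | np.ndarray,
    rule: str = "eigenvalue",
    variance_threshold: float = 0.75,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the Pearson correlation matrix.

    Retention rules: ``eigenvalue`` keeps components with eigenvalue > 1;
    ``variance`` keeps the smallest number of components whose cumulative
    explained variance reaches ``variance_threshold`` (the conventional
    70-80% band).  An explicit ``n_components`` overrides both.
    """
    m = _as_matrix(items)
    corr, labels, _dropped = pearson_matrix(m)
    p = corr.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # reproducible sign convention: largest-|.| entry of each eigenvector positive
    for j in range(p):
        i_max = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i_max, j] < 0:
            eigvec[:, j] *= -1.0
    loadings = eigvec * np.sqrt(eigval)
    explained = 100.0 * eigval / p
    cumulative = np.cumsum(explained)
    if n_components is not None:
        kept = int(n_components)
        fired = "explicit"
    elif rule == "eigenvalue":
        kept = max(1, int(np.sum(eigval > 1.0)))
        fired = "eigenvalue>1"
    elif rule == "variance":
        kept = int(np.searchsorted(cumulative, 100.0 * variance_threshold) + 1)
        kept = min(max(kept, 1), p)
        fired = f"cumulative variance >= {variance_threshold:.0%}"
    else:
        raise DomainError(f"unknown retention rule {rule!r}")
    if not (1 <= kept <= p):
        raise DomainError(f"n_components must be within 1..{p}, got {kept}")
    communalities = (loadings[:, :kept] ** 2).sum(axis=1)
    return PCAResult(
        eigenvalues=eigval,
        loadings=loadings,
        explained=explained,
        cumulative=cumulative,
        n_components=kept,
        rule=fired,
        communalities=communalities,
        items=labels,
    )


# ---------------------------------------------------------------------------
# direct oblimin rotation (gradient projection)
# ---------------------------------------------------------------------------

def _oblimin_criterion(L: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Direct oblimin criterion value and its gradient with respect to L.

    gamma = 0 is direct quartimin, the common software default when
    "Oblimin" is requested without a parameter.
    """
    p, k = L.shape
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    X = L2 @ N
    if gamma != 0.0:
        X = (np.eye(p) - np.full((p, p), gamma / p)) @ X
    f = float(np.sum(L2 * X)) / 4.0
    grad = L * X
    return f, grad


class RotationConvergenceError(RuntimeError):
    """Gradient-projection rotation failed to converge."""

    def __init__(self, criterion: float, iterations: int):
        self.criterion = criterion
        super().__init__(
            f"oblimin rotation did not converge in {iterations} iterations "
            f"(criterion {criterion:.6g})"
        )


def _gpa_oblique(
    A: np.ndarray, gamma: float, T0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Gradient-projection algorithm for oblique rotation.

    Minimizes the oblimin criterion over rotation matrices T with
    unit-length columns; returns (pattern, Phi, criterion, converged).
    """
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, grad = _oblimin_criterion(L, gamma)
    G = -(L.T @ grad @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            converged = True
            break
        al = 2.0 * al
        for _half in range(20):
            X = T - al * Gp
            nv = np.sqrt((X**2).sum(axis=0))
            Tt = X @ np.diag(1.0 / nv)
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, grad = _oblimin_criterion(L, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al = al / 2.0
        T = Tt
        f = ft
        G = -(L.T @ grad @ Ti).T
    Phi = T.T @ T
    return L, Phi, f, converged


def oblimin_rotate(
    loadings: np.ndarray,
    gamma: float = 0.0,
    kaiser: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
    restarts: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct oblimin rotation of an unrotated loading matrix.

    Rows are Kaiser-normalized before rotation and denormalized after.
    Multiple seeded random starts guard against local minima; the solution
    with the lowest criterion wins.  Returns ``(pattern, structure, Phi)``
    with ``structure = pattern @ Phi``.  Each pattern column's sign is
    fixed so its largest-magnitude loading is positive.
    """
    A = np.asarray(loadings, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise DomainError("rotation needs at least 2 retained components")
    p, k = A.shape
    h = np.sqrt((A**2).sum(axis=1))
    if kaiser:
        if np.any(h <= 0):
            raise DomainError("Kaiser normalization impossible: zero-communality row")
        A_work = A / h[:, None]
    else:
        A_work = A

    rng = np.random.default_rng(seed)
    starts = [np.eye(k)]
    for _ in range(max(0, restarts - 1)):
        Q, _ = np.linalg.qr(rng.normal(size=(k, k)))
        starts.append(Q / np.sqrt((Q**2).sum(axis=0)))

    best = None
    last_f = np.inf
    for T0 in starts:
        L, Phi, f, ok = _gpa_oblique(A_work, gamma, T0, tol, max_iter)
        last_f = min(last_f, f)
        if ok and (best is None or f < best[2]):
            best = (L, Phi, f)
    if best is None:
        raise RotationConvergenceError(last_f, max_iter)
    L, Phi, _f = best
    if kaiser:
        L = L * h[:, None]
    # sign convention for reproducible reports
    for j in range(k):
        i_max = int(np.argmax(np.abs(L[:, j])))
        if L[i_max, j] < 0:
            L[:, j] *= -1.0
            Phi[j, :] *= -1.0
            Phi[:, j] *= -1.0
    structure = L @ Phi
    return L, structure, Phi


def oblimin_criterion(loadings: np.ndarray, gamma: float = 0.0) -> float:
    """Criterion value of a (rotated) pattern matrix; exposed for
    brute-force comparison against random oblique rotations."""
    f, _ = _oblimin_criterion(np.asarray(loadings, dtype=float), gamma)
    return f


def drop_suggestions(
    pattern: np.ndarray,
    items: Sequence[str] | None = None,
    threshold: float = 0.4,
    pcs: Sequence[int] = (0, 1),
) -> list[str]:
    """Items whose |pattern loading| is below ``threshold`` on *all* of the
    given components (0-based indices; default the first two)."""
    P = np.asarray(pattern, dtype=float)
    labels = list(items) if items is not None else [f"item{i+1}" for i in range(P.shape[0])]
    k = P.shape[1]
    use = [j for j in pcs if j < k]
    if not use:
        raise DomainError("no valid component indices for drop rule")
    out = []
    for i, label in enumerate(labels):
        if all(abs(P[i, j]) < threshold for j in use):
            out.append(label)
    return out


def indicator_item_matrix(
    dataset,
    scenario,
    pillar: str = "vulnerability",
    component: str | None = None,
) -> ItemMatrix:
    """Facility x indicator score matrix for one pillar (or one
    vulnerability component block) of a scenario-applied survey dataset.

    The suite requires complete matrices: a facility missing every
    sub-indicator of a block indicator raises rather than being imputed.
    """
    from .scenario import facility_indicator_values  # local: avoid cycle

    catalog = dataset.catalog
    indicators = [
        n for n in catalog.indicators(pillar)
        if component is None or n.component == component
    ]
    if not indicators:
        raise DomainError(f"no indicators for pillar={pillar!r} component={component!r}")
    rows = []
    for record in dataset.records:
        values = facility_indicator_values(record, scenario, catalog)
        row = []
        for ind in indicators:
            v = values.get(ind.id)
            if v is None:
                raise DomainError(
                    f"facility {record.facility_id}: no data for indicator "
                    f"{ind.id}; the robustness suite requires complete matrices"
                )
            row.append(v)
        rows.append(row)
    return ItemMatrix(np.asarray(rows, dtype=float), tuple(i.id for i in indicators))


@dataclass(frozen=True)
class RobustnessReport:
    """Full reliability / sampling-adequacy / PCA report for one item block."""

    items: tuple[str, ...]
    n: int
    alpha: float
    item_total: Mapping[str, Mapping[str, float | bool]]
    kmo_overall: float
    kmo_per_variable: np.ndarray
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    explained: np.ndarray
    cumulative: np.ndarray
    n_components: int
    selection_rule: str
    communalities: np.ndarray
    pattern: np.ndarray | None
    structure: np.ndarray | None
    component_correlations: np.ndarray | None
    pearson: np.ndarray
    indicator_pillar_correlations: Mapping[str, float]
    drop_suggestions: tuple[str, ...]
    dropped_constant: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "items": list(self.items),
            "n": self.n,
            "alpha": self.alpha,
            "item_total": {k: dict(v) for k, v in self.item_total.items()},
            "kmo": {"overall": self.kmo_overall,
                    "per_variable": arr(self.kmo_per_variable)},
            "bartlett": {"chi2": self.bartlett_chi2, "df": self.bartlett_df,
                         "p": self.bartlett_p},
            "eigenvalues": arr(self.eigenvalues),
            "explained_variance": arr(self.explained),
            "cumulative_variance": arr(self.cumulative),
            "n_components": self.n_components,
            "selection_rule": self.selection_rule,
            "communalities": arr(self.communalities),
            "pattern": arr(self.pattern),
            "structure": arr(self.structure),
            "component_correlations": arr(self.component_correlations),
            "pearson": arr(self.pearson),
            "indicator_pillar_correlations": dict(self.indicator_pillar_correlations),
            "drop_suggestions": list(self.drop_suggestions),
            "dropped_constant": list(self.dropped_constant),
            "warnings": list(self.warnings),
        }


def analyze_block(
    items: ItemMatrix | np.ndarray,
    rule: str = "eigenvalue",
    variance_threshold: float = 0.75,
    loading_threshold: float = 0.4,
    item_total_threshold: float = 0.3,
    gamma: float = 0.0,
    seed: int = 0,
) -> RobustnessReport:
    """Run the complete robustness suite on one item block.

    Performs reliability, KMO/Bartlett, correlation-matrix PCA with the
    chosen retention rule, oblimin rotation (when >= 2 components are
    retained) and the |loading| drop rule; indicator-vs-pillar-score
    correlations use the equal-weighted row mean as the pillar score.
    """
    m = _as_matrix(items)
    warnings: list[str] = []
    if m.n < 30:
        warnings.append(
            f"small sample: n={m.n} < 30; data-driven robustness statistics "
            "are fragile at this size"
        )
    corr, labels, dropped = pearson_matrix(m)
    if dropped:
        warnings.append(f"zero-variance item(s) dropped: {list(dropped)}")
        m = m.select(labels)
    res = pca(m, rule=rule, variance_threshold=variance_threshold)
    if res.n_components >= 2:
        pattern, structure, phi = oblimin_rotate(
            res.loadings[:, : res.n_components], gamma=gamma, seed=seed
        )
        drops = tuple(drop_suggestions(pattern, labels, loading_threshold))
    else:
        pattern = structure = phi = None
        drops = ()
        warnings.append("single retained component: rotation skipped")
    pillar_score = m.values.mean(axis=1)
    corr_with_pillar = {}
    for i, label in enumerate(labels):
        col = m.values[:, i]
        if col.std(ddof=1) > 0 and pillar_score.std(ddof=1) > 0:
            corr_with_pillar[label] = float(np.corrcoef(col, pillar_score)[0, 1])
        else:
            corr_with_pillar[label] = float("nan")
    chi2, df, pval = bartlett(corr, m.n)
    kmo_overall, kmo_per = kmo(corr)
    return RobustnessReport(
        items=labels,
        n=m.n,
        alpha=cronbach_alpha(m),
        item_total=item_total(m, flag_threshold=item_total_threshold),
        kmo_overall=kmo_overall,
        kmo_per_variable=kmo_per,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
        eigenvalues=res.eigenvalues,
        explained=res.explained,
        cumulative=res.cumulative,
        n_components=res.n_components,
        selection_rule=res.rule,
        communalities=res.communalities,
        pattern=pattern,
        structure=structure,
        component_correlations=phi,
        pearson=corr,
        indicator_pillar_correlations=corr_with_pillar,
        drop_suggestions=drops,
        dropped_constant=dropped,
        warnings=tuple(warnings),
    )
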