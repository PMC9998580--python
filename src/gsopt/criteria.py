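"""Training-set evaluation criteria: CDmean, CDMEAN2, Rscore and the
gAvg_GRM family, with targeted/untargeted target-population resolution.

All criteria score a candidate training set (TRS) for its ability to support
genomic prediction over a target population (TP); larger is better and every
criterion is permutation-invariant in the ordering of its id sets.

Target-population rules
-----------------------
Targeted optimization uses the test set as TP for every criterion. In the
untargeted scenario the test set is unknown and a placeholder is used:

========== =========================================
criterion   untargeted target population
========== =========================================
cdmean      remaining set (candidate - training)
cdmean2     remaining set
rscore      candidate set
avg_grm     candidate set
avg_grm_minmax  remaining set
avg_grm_self    none (TP not part of the criterion)
========== =========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_RIDGE, MarkerMatrix, RelationshipMatrix, ScoreMatrix

CRITERION_NAMES = ("cdmean", "cdmean2", "rscore", "avg_grm", "avg_grm_self", "avg_grm_minmax")

#: (a, b) weights of the relationship-balance criterion for the named variants
GAVG_WEIGHTS = {"avg_grm": (1.0, 0.0), "avg_grm_self": (0.0, 1.0), "avg_grm_minmax": (1.0, 1.0)}


@dataclass
class CriterionSpec:
    """Which criterion to optimize and under which scenario.

    ``a`` and ``b`` weight the mean training-target relationship against the
    mean within-training relationship for the avg_grm family; ``lambda_`` is
    the mixed-model shrinkage (noise-to-genetic variance ratio) used by
    cdmean/cdmean2 and the ridge penalty of rscore.
    """

    name: str
    scenario: str = "untargeted"
    a: float = None
    b: float = None
    lambda_: float = 1.0
    n_components: int | None = None

    def __post_init__(self) -> None:
        if self.name not in CRITERION_NAMES:
            raise ValueError(f"unknown criterion {self.name!r}")
        if self.scenario not in ("targeted", "untargeted"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.name in GAVG_WEIGHTS:
            a, b = GAVG_WEIGHTS[self.name]
            if self.a is None:
                self.a = a
            if self.b is None:
                self.b = b
            if (self.a, self.b) != (a, b):
                raise ValueError(
                    f"{self.name} requires weights (a, b) = {GAVG_WEIGHTS[self.name]}"
                )
        if self.name == "avg_grm_self" and self.scenario == "targeted":
            raise ValueError("targeted optimization is not possible for avg_grm_self")
        if self.a is not None and self.a < 0 or self.b is not None and self.b < 0:
            raise ValueError("weights a, b must be non-negative")
        if self.lambda_ <= 0:
            raise ValueError("shrinkage lambda must be positive")


@dataclass
class TargetResolution:
    training_ids: list
    target_ids: list
    provenance: str  # "test set" | "remaining set" | "candidate set" | "none"


def resolve_target_population(
    spec: CriterionSpec, candidate_ids, training_ids, test_ids=None
) -> TargetResolution:
    """Resolve the target population for a criterion/scenario combination."""
    candidate = list(candidate_ids)
    training = list(training_ids)
    cand_set = set(candidate)
    if not set(training) <= cand_set:
        raise ValueError("training ids must be a subset of the candidate set")
    if spec.scenario == "targeted":
        if spec.name == "avg_grm_self":
            raise ValueError("targeted optimization is not possible for avg_grm_self")
        if not test_ids:
            raise ValueError("targeted optimization requires test ids")
        if cand_set & set(test_ids):
            raise ValueError("test ids must be disjoint from the candidate set")
        return TargetResolution(training, list(test_ids), "test set")
    if spec.name in ("cdmean", "cdmean2", "avg_grm_minmax"):
        train_set = set(training)
        remaining = [s for s in candidate if s not in train_set]
        return TargetResolution(training, remaining, "remaining set")
    if spec.name in ("rscore", "avg_grm"):
        return TargetResolution(training, candidate, "candidate set")
    return TargetResolution(training, [], "none")  # avg_grm_self


# ---------------------------------------------------------------------------
# CDmean
# ---------------------------------------------------------------------------


def _cd_union(A: RelationshipMatrix, training_ids, target_ids):
    """Submatrix of A over training ∪ target (in A's id order) plus index sets."""
    train_set, target_set = set(training_ids), set(target_ids)
    union = [s for s in A.ids if s in train_set or s in target_set]
    if len(train_set | target_set) != len(union):
        raise KeyError("training/target ids missing from the relationship matrix")
    pos = {s: i for i, s in enumerate(union)}
    a_sub = A.submatrix(union)
    t_idx = np.array([pos[s] for s in union if s in train_set], dtype=int)
    v_idx = np.array([pos[s] for s in union if s in target_set], dtype=int)
    return a_sub, t_idx, v_idx


def _ztmz(n: int, train_idx: np.ndarray) -> np.ndarray:
    """Z'MZ for intercept-only fixed effects: the training block of
    I - 11'/t, embedded in an n x n matrix of zeros."""
    t = train_idx.size
    out = np.zeros((n, n))
    out[np.ix_(train_idx, train_idx)] = np.eye(t) - 1.0 / t
    return out


def cdmean(
    A: RelationshipMatrix,
    training_ids,
    target_ids,
    lambda_: float = 1.0,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Mean coefficient of determination of the target genetic values.

    CD_i = [A - lambda (Z'MZ + lambda A^-1)^-1]_ii / A_ii averaged over the
    target individuals, with Z the incidence of the training rows and M the
    projector orthogonal to the intercept on the training set. A is restricted
    to training ∪ target and ridged before inversion.
    """
    if not len(training_ids) or not len(target_ids):
        raise ValueError("training and target sets must be nonempty")
    a_sub, t_idx, v_idx = _cd_union(A, training_ids, target_ids)
    n = a_sub.shape[0]
    a_r = a_sub + ridge * np.eye(n)
    try:
        a_inv = np.linalg.inv(a_r)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("relationship matrix singular after ridge") from exc
    coeff = _ztmz(n, t_idx) + lambda_ * a_inv
    try:
        c_inv = np.linalg.inv(coeff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("mixed-model coefficient matrix singular") from exc
    cd = (np.diag(a_r) - lambda_ * np.diag(c_inv)) / np.diag(a_r)
    return float(np.mean(cd[v_idx]))


def cdmean2(
    A: RelationshipMatrix,
    training_ids,
    target_ids,
    lambda_: float = 1.0,
    n_components: int | None = None,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """CDmean on a rank-reduced spectral approximation of A.

    The ridged submatrix over training ∪ target is eigendecomposed and the
    leading ``n_components`` components retained: A ≈ Q Q' with
    Q = V_k diag(sqrt(l_k)). Then
    CD_i = (q_i.q_i - lambda q_i'(Q_t'M Q_t + lambda I)^-1 q_i) / q_i.q_i,
    which reduces the per-evaluation cost to a k x k inversion and equals
    :func:`cdmean` exactly when n_components = n.
    """
    if not len(training_ids) or not len(target_ids):
        raise ValueError("training and target sets must be nonempty")
    a_sub, t_idx, v_idx = _cd_union(A, training_ids, target_ids)
    n = a_sub.shape[0]
    k = n if n_components is None else int(n_components)
    if not 1 <= k <= n:
        raise ValueError(f"n_components must be in [1, {n}]")
    evals, evecs = np.linalg.eigh(a_sub + ridge * np.eye(n))
    order = np.argsort(evals)[::-1][:k]
    lam_k = np.clip(evals[order], 0.0, None)
    q = evecs[:, order] * np.sqrt(lam_k)
    return cd_from_scores(q, t_idx, v_idx, lambda_)


def cd_from_scores(q: np.ndarray, train_idx, target_idx, lambda_: float = 1.0) -> float:
    """CDmean in a low-rank score basis: rows of ``q`` satisfy A ≈ Q Q'."""
    qt = q[np.asarray(train_idx, dtype=int)]
    qt_c = qt - qt.mean(axis=0, keepdims=True)
    k = q.shape[1]
    coeff = qt_c.T @ qt_c + lambda_ * np.eye(k)
    try:
        c_inv = np.linalg.inv(coeff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("score-space coefficient matrix singular") from exc
    qv = q[np.asarray(target_idx, dtype=int)]
    prior = np.einsum("ij,ij->i", qv, qv)
    pev = lambda_ * np.einsum("ij,jk,ik->i", qv, c_inv, qv)
    if np.any(prior <= 0):
        raise ValueError("zero prior variance for a target individual")
    return float(np.mean((prior - pev) / prior))


# ---------------------------------------------------------------------------
# Rscore
# ---------------------------------------------------------------------------


def _gram(x, sample_ids=None) -> tuple[np.ndarray, list]:
    """Gram matrix of the column-centered data, plus its id order."""
    if isinstance(x, MarkerMatrix):
        xc = x.centered()
        ids = list(x.sample_ids)
    elif isinstance(x, ScoreMatrix):
        xc = x.component_scores - x.component_scores.mean(axis=0, keepdims=True)
        ids = list(x.sample_ids)
    else:
        xc = np.asarray(x, dtype=float)
        xc = xc - xc.mean(axis=0, keepdims=True)
        ids = list(sample_ids) if sample_ids is not None else list(range(xc.shape[0]))
    return xc @ xc.T, ids


def rscore(
    x,
    training_ids,
    target_ids,
    lambda_: float = 1.0,
    sample_ids=None,
    gram: np.ndarray | None = None,
) -> float:
    """Expected correlation between ridge GEBVs and target phenotypes.

    Under the working prior of unit marker-effect variance and residual
    variance ``lambda_``, training phenotypes y_t map to target GEBVs through
    H = G_vt (G_tt + lambda I)^-1 with G the Gram matrix of the centered
    marker data. The criterion is

        E corr = tr(P G_vt H') / sqrt( tr(P H (G_tt + lambda I) H') *
                                       tr(P (G_vv + lambda I)) )

    with P the centering projector on the target set. It depends on the
    markers only through G, so substituting the full set of n principal
    components leaves it unchanged.
    """
    if not len(training_ids) or not len(target_ids):
        raise ValueError("training and target sets must be nonempty")
    if gram is not None:
        g = gram
        ids = list(sample_ids)
    else:
        g, ids = _gram(x, sample_ids)
    if np.allclose(g, 0.0, atol=1e-12):
        raise ValueError("degenerate marker matrix: all rows identical")
    lookup = {s: i for i, s in enumerate(ids)}
    t = np.array([lookup[s] for s in training_ids], dtype=int)
    v = np.array([lookup[s] for s in target_ids], dtype=int)
    g_tt = g[np.ix_(t, t)]
    g_vt = g[np.ix_(v, t)]
    g_vv = g[np.ix_(v, v)]
    nt, nv = t.size, v.size
    h = g_vt @ np.linalg.inv(g_tt + lambda_ * np.eye(nt))

    def center(mat: np.ndarray) -> np.ndarray:
        return mat - mat.mean(axis=0, keepdims=True)

    num = float(np.einsum("ij,ij->", center(g_vt), h))
    den1 = float(np.einsum("ij,ij->", center(h @ (g_tt + lambda_ * np.eye(nt))), h))
    den2 = float(np.trace(center(g_vv + lambda_ * np.eye(nv))))
    if den1 <= 0 or den2 <= 0:
        raise ValueError("degenerate inputs: zero predicted or target variance")
    return num / np.sqrt(den1 * den2)


# ---------------------------------------------------------------------------
# gAvg_GRM family
# ---------------------------------------------------------------------------


def gavg_grm(A: RelationshipMatrix, training_ids, target_ids, a: float, b: float) -> float:
    """Relationship-balance criterion
    a * mean(A[TRS, TP]) - b * mean(A[TRS, TRS]) (diagonal included)."""
    if not len(training_ids):
        raise ValueError("training set must be nonempty")
    value = 0.0
    if a != 0.0:
        if not len(target_ids):
            raise ValueError("a > 0 requires a nonempty target population")
        value += a * float(A.submatrix(training_ids, target_ids).mean())
    if b != 0.0:
        value -= b * float(A.submatrix(training_ids, training_ids).mean())
    return value


# ---------------------------------------------------------------------------
# Evaluator factory for the subset search
# ---------------------------------------------------------------------------


def make_evaluator(
    spec: CriterionSpec,
    candidate_ids,
    test_ids=None,
    A: RelationshipMatrix | None = None,
    markers=None,
    ridge: float = DEFAULT_RIDGE,
):
    """Return ``evaluate(training_ids) -> float`` for a criterion spec.

    Resolves the target population per call (the untargeted remaining set
    depends on the training set itself). Gram matrices and spectral bases are
    precomputed once so repeated evaluations inside a search stay cheap.
    """
    candidate = list(candidate_ids)
    if spec.name in GAVG_WEIGHTS or spec.name in ("cdmean", "cdmean2"):
        if A is None:
            raise ValueError(f"{spec.name} requires a relationship matrix")
    if spec.name == "rscore":
        if markers is None:
            raise ValueError("rscore requires marker data or PC scores")
        universe = candidate + [s for s in (test_ids or []) if s not in set(candidate)]
        gram_full, gram_ids = _gram(markers)
        keep = [i for i, s in enumerate(gram_ids) if s in set(universe)]
        gram_ids = [gram_ids[i] for i in keep]
        gram_full = gram_full[np.ix_(keep, keep)]

    if spec.name == "cdmean2":
        # one spectral basis over candidate ∪ test, reused for every subset
        universe = candidate + [s for s in (test_ids or []) if s not in set(candidate)]
        a_sub = A.submatrix(universe) + ridge * np.eye(len(universe))
        evals, evecs = np.linalg.eigh(a_sub)
        k = spec.n_components or len(universe)
        order = np.argsort(evals)[::-1][:k]
        q_basis = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))
        upos = {s: i for i, s in enumerate(universe)}

    def evaluate(training_ids) -> float:
        res = resolve_target_population(spec, candidate, training_ids, test_ids)
        if spec.name == "cdmean":
            return cdmean(A, res.training_ids, res.target_ids, spec.lambda_, ridge)
        if spec.name == "cdmean2":
            t_idx = [upos[s] for s in res.training_ids]
            v_idx = [upos[s] for s in res.target_ids]
            return cd_from_scores(q_basis, t_idx, v_idx, spec.lambda_)
        if spec.name == "rscore":
            return rscore(
                None,
                res.training_ids,
                res.target_ids,
                spec.lambda_,
                sample_ids=gram_ids,
                gram=gram_full,
            )
        return gavg_grm(A, res.training_ids, res.target_ids, spec.a, spec.b)

    return evaluate
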