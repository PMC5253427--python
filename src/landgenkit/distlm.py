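"""Distance-based linear models (McArdle–Anderson trace machinery).

A response distance matrix D is Gower-centered into G; for a design matrix X
with hat matrix H, the explained trace tr(HGH) plays the role of a regression
sum of squares.  The pseudo-F statistic

    F = [tr(HGH) / q] / [tr((I-H) G (I-H)) / (n - q - 1)]

reduces exactly to the classical ANOVA/regression F when D is the Euclidean
distance of a single response variable.  Percent variance explained is
100 * tr(HGH) / tr(G) (marginal) or the added-trace analogue (conditional,
which may legitimately be negative for non-Euclidean D).

Permutation schemes: raw-unit permutation of D for marginal tests;
Freedman–Lane residual permutation under the reduced model for conditional
and sequential tests.  Categorical predictors are dummy-coded against a
first-level reference; declared groups (e.g. coordinates = longitude +
latitude) enter and exit as one block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DistanceMatrix
from .errors import ValidationError

TEST_TYPES = ("marginal", "conditional", "sequential")


@dataclass
class Predictor:
    """One tested term: a named continuous/categorical column or a block of columns."""

    label: str
    columns: np.ndarray  # (n, q) design columns, already coded
    q: int


@dataclass
class PredictorSet:
    """Named predictors over aligned sampling units.

    ``variables`` maps label -> column name(s) in ``data``; categorical columns
    (object/str dtype) are dummy-coded with the first observed level as
    reference.  Units with missing predictor values must be dropped upstream.
    """

    data: pd.DataFrame
    unit_labels: list[str]
    groups: dict = field(default_factory=dict)  # label -> list of column names

    def __post_init__(self) -> None:
        if len(self.data) != len(self.unit_labels):
            raise ValidationError("predictor rows do not match unit labels")
        if self.data.isna().any().any():
            bad = [c for c in self.data.columns if self.data[c].isna().any()]
            raise ValidationError(f"predictor columns with missing values: {bad}")

    def term_labels(self) -> list[str]:
        grouped_cols = {c for cols in self.groups.values() for c in cols}
        singles = [c for c in self.data.columns if c not in grouped_cols]
        return list(self.groups) + singles

    def term(self, label: str) -> Predictor:
        cols = self.groups.get(label, [label])
        blocks = []
        for c in cols:
            if c not in self.data.columns:
                raise ValidationError(f"unknown predictor column {c!r}")
            col = self.data[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = list(dict.fromkeys(col))
                if len(levels) < 2:
                    raise ValidationError(f"categorical predictor {c!r} has < 2 levels")
                for lev in levels[1:]:
                    blocks.append((col == lev).to_numpy(dtype=float)[:, None])
            else:
                blocks.append(col.to_numpy(dtype=float)[:, None])
        X = np.hstack(blocks)
        return Predictor(label=label, columns=X, q=X.shape[1])


@dataclass
class DistlmRow:
    predictor: str
    pseudo_F: float
    p: float
    pct_var: float
    test_type: str
    q: int


def gower_center(D: DistanceMatrix) -> np.ndarray:
    """Gower-centered inner-product matrix G = J (-D^2 / 2) J with J = I - 11'/n."""
    d = D.values
    if np.isnan(d).any():
        raise ValidationError("Gower centering requires a complete distance matrix")
    n = d.shape[0]
    A = -0.5 * d * d
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    """Hat matrix via QR; raises on a singular (collinear) design."""
    n = X.shape[0]
    Xi = np.column_stack([np.ones(n), X])
    q, r = np.linalg.qr(Xi)
    diag = np.abs(np.diag(r))
    if (diag < 1e-10 * max(1.0, diag.max())).any():
        raise ValidationError("singular design matrix (constant or collinear columns)")
    return q @ q.T


def _trace_prod(H: np.ndarray, G: np.ndarray) -> float:
    # tr(HGH) = tr(H G) for idempotent symmetric H
    return float((H * G).sum())


def _pseudo_f(G: np.ndarray, H: np.ndarray, q: int) -> tuple[float, float, float]:
    n = G.shape[0]
    tr_g = float(np.trace(G))
    explained = _trace_prod(H, G)
    I = np.eye(n)
    residual = float(((I - H) * ((I - H) @ G)).sum())  # tr((I-H)G(I-H))
    df2 = n - q - 1
    F = (explained / q) / (residual / df2)
    return F, explained, tr_g


def distlm_marginal(
    D: DistanceMatrix,
    preds: PredictorSet,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> list[DistlmRow]:
    """Variation explained by each predictor (or declared group) alone."""
    if D.labels != preds.unit_labels:
        raise ValidationError("distance matrix and predictors are not aligned")
    G = gower_center(D)
    n = G.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for label in preds.term_labels():
        term = preds.term(label)
        H = _hat(term.columns)
        F_obs, explained, tr_g = _pseudo_f(G, H, term.q)
        count = 1
        for _ in range(n_perm):
            pi = rng.permutation(n)
            Gp = G[np.ix_(pi, pi)]
            F_p, _, _ = _pseudo_f(Gp, H, term.q)
            if F_p >= F_obs:
                count += 1
        rows.append(
            DistlmRow(
                predictor=label,
                pseudo_F=F_obs,
                p=count / (n_perm + 1),
                pct_var=100.0 * explained / tr_g,
                test_type="marginal",
                q=term.q,
            )
        )
    return rows


def _conditional_stats(
    G: np.ndarray, H_cov: np.ndarray, H_full: np.ndarray, q_added: int, q_full: int
) -> tuple[float, float]:
    n = G.shape[0]
    added = _trace_prod(H_full, G) - _trace_prod(H_cov, G)
    I = np.eye(n)
    resid = float(((I - H_full) * ((I - H_full) @ G)).sum())
    F = (added / q_added) / (resid / (n - q_full - 1))
    return F, added


def distlm_conditional(
    D: DistanceMatrix,
    preds: PredictorSet,
    covariates: str | list[str],
    n_perm: int = 9_999,
    seed: int | None = None,
) -> list[DistlmRow]:
    """Added variation of each predictor after fitting the covariate block.

    Permutation is Freedman–Lane: the Gower matrix of covariate-model
    residuals is permuted under the reduced model.
    """
    if D.labels != preds.unit_labels:
        raise ValidationError("distance matrix and predictors are not aligned")
    cov_labels = [covariates] if isinstance(covariates, str) else list(covariates)
    G = gower_center(D)
    n = G.shape[0]
    X_cov = np.hstack([preds.term(c).columns for c in cov_labels])
    H_cov = _hat(X_cov)
    R_cov = np.eye(n) - H_cov
    G_res = R_cov @ G @ R_cov
    rng = np.random.default_rng(seed)
    rows = []
    tr_g = float(np.trace(G))
    skip = set(cov_labels)
    for label in preds.term_labels():
        if label in skip:
            continue
        term = preds.term(label)
        X_full = np.hstack([X_cov, term.columns])
        H_full = _hat(X_full)
        q_full = X_full.shape[1]
        F_obs, added = _conditional_stats(G, H_cov, H_full, term.q, q_full)
        count = 1
        for _ in range(n_perm):
            pi = rng.permutation(n)
            Gp = G_res[np.ix_(pi, pi)]
            F_p, _ = _conditional_stats(Gp, H_cov, H_full, term.q, q_full)
            if F_p >= F_obs:
                count += 1
        rows.append(
            DistlmRow(
                predictor=label,
                pseudo_F=F_obs,
                p=count / (n_perm + 1),
                pct_var=100.0 * added / tr_g,
                test_type="conditional",
                q=term.q,
            )
        )
    return rows


def distlm_forward(
    D: DistanceMatrix,
    preds: PredictorSet,
    n_perm: int = 9_999,
    seed: int | None = None,
    enter_all: bool = True,
    alpha: float = 0.05,
) -> list[DistlmRow]:
    """Greedy forward selection, reporting per-step added pseudo-F, p, %var.

    At each step the predictor maximizing the added explained trace enters;
    its p-value is conditional on the previously entered terms (Freedman–Lane).
    With ``enter_all`` every term eventually enters (the default, matching a
    full sequential table); otherwise selection stops when no candidate
    reaches ``alpha``.
    """
    if D.labels != preds.unit_labels:
        raise ValidationError("distance matrix and predictors are not aligned")
    G = gower_center(D)
    n = G.shape[0]
    rng = np.random.default_rng(seed)
    remaining = preds.term_labels()
    entered_cols: list[np.ndarray] = []
    rows: list[DistlmRow] = []
    tr_g = float(np.trace(G))
    while remaining:
        H_base = _hat(np.hstack(entered_cols)) if entered_cols else np.full((n, n), 1.0 / n)
        base_explained = _trace_prod(H_base, G)
        best = None
        for label in remaining:
            term = preds.term(label)
            X_full = (
                np.hstack(entered_cols + [term.columns]) if entered_cols else term.columns
            )
            try:
                H_full = _hat(X_full)
            except ValidationError:
                # collinear with already-entered terms: zero added variation
                best_candidate = (0.0, label, term, None, X_full.shape[1])
                if best is None or best[0] < 0:
                    best = best_candidate
                continue
            added = _trace_prod(H_full, G) - base_explained
            cand = (added, label, term, H_full, X_full.shape[1])
            if best is None or added > best[0]:
                best = cand
        added, label, term, H_full, q_full = best
        if H_full is None:
            rows.append(
                DistlmRow(
                    predictor=label, pseudo_F=np.nan, p=np.nan, pct_var=0.0,
                    test_type="sequential", q=term.q,
                )
            )
            remaining.remove(label)
            continue
        F_obs, added = _conditional_stats(G, H_base, H_full, term.q, q_full)
        R_base = np.eye(n) - H_base
        G_res = R_base @ G @ R_base
        count = 1
        for _ in range(n_perm):
            pi = rng.permutation(n)
            Gp = G_res[np.ix_(pi, pi)]
            F_p, _ = _conditional_stats(Gp, H_base, H_full, term.q, q_full)
            if F_p >= F_obs:
                count += 1
        p = count / (n_perm + 1)
        if not enter_all and p > alpha:
            break
        rows.append(
            DistlmRow(
                predictor=label,
                pseudo_F=F_obs,
                p=p,
                pct_var=100.0 * added / tr_g,
                test_type="sequential",
                q=term.q,
            )
        )
        remaining.remove(label)
        entered_cols.append(term.columns)
    return rows


def migration_to_distance(m_values: np.ndarray, labels: list[str], direction: str) -> DistanceMatrix:
    """Convert a directional migration matrix into a distance-like matrix 1 - m.

    ``direction="upper"`` takes, for each unordered pair {i, j} with i < j, the
    rate m[i][j] (into i from j); ``"lower"`` takes m[j][i].  The two halves of
    a migration matrix thus become two symmetric dissimilarity matrices.
    """
    m = np.asarray(m_values, dtype=float)
    k = m.shape[0]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rate = m[i, j] if direction == "upper" else m[j, i]
            out[i, j] = out[j, i] = 1.0 - rate
    return DistanceMatrix(labels=labels, values=out, kind="other")


def distlm_population_level(
    fst: DistanceMatrix,
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    attrs,
    geo_distance: DistanceMatrix,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> dict:
    """Population-level tests of N_e and N_c against F_ST and dispersal matrices.

    For each response (F_ST, M1, M2): marginal tests of N_e and N_c, plus
    conditional tests with mean geographic distance as covariate; F_ST is used
    as an additional covariate when the response is a dispersal matrix.
    Delegates to :func:`distlm_marginal` / :func:`distlm_conditional`.
    """
    labels = fst.labels
    if len(labels) < 4:
        raise ValidationError("population-level DISTLM needs at least 4 populations")
    order = {p: i for i, p in enumerate(attrs.population_ids)}
    idx = [order[p] for p in labels]
    # geographic covariate: mean distance from each population to all others
    gd = geo_distance.align(labels).values
    mean_geo = gd.sum(axis=1) / (len(labels) - 1)
    base = pd.DataFrame(
        {
            "n_effective": attrs.n_effective[idx],
            "n_census": attrs.n_census[idx],
            "mean_geo_distance": mean_geo,
        }
    )
    results: dict = {}
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(6)
    responses = {"fst": fst, "m1": m1.align(labels), "m2": m2.align(labels)}
    for k, (name, resp) in enumerate(responses.items()):
        data = base.copy()
        if name != "fst":
            fvec = fst.values
            data["mean_fst"] = fvec.sum(axis=1) / (len(labels) - 1)
        preds = PredictorSet(data=data, unit_labels=list(labels))
        marg = distlm_marginal(resp, preds, n_perm=n_perm, seed=int(seeds[2 * k] % 2**31))
        cov = ["mean_geo_distance"] + (["mean_fst"] if name != "fst" else [])
        cond = distlm_conditional(
            resp, preds, covariates=cov, n_perm=n_perm, seed=int(seeds[2 * k + 1] % 2**31)
        )
        keep = {"n_effective", "n_census"}
        results[name] = {
            "marginal": [r for r in marg if r.predictor in keep],
            "conditional": [r for r in cond if r.predictor in keep],
        }
    return results
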