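"""Regularized iterative FAMD imputation of missing mixed-data cells.

An EM-like loop alternates between fitting the FAMD decomposition on a
completed table and refilling the missing cells from a low-rank
reconstruction with shrunken singular values.  Quantitative cells start
at the column mean and categorical cells at the observed category
proportions (a fuzzy membership); each iteration re-encodes the table
with freshly computed standard deviations and category proportions,
truncates the SVD at ``ncp`` components with singular values shrunk by
(d_l^2 − σ̂^2)/d_l — σ̂^2 being the mean of the discarded eigenvalues —
and overwrites only the originally missing cells with the
back-transformed fit.  Regularization keeps the iteration from
overfitting noise when the number of components approaches the rank.

Observed cells are never touched; missing categorical cells retain their
fuzzy memberships so the downstream decomposition can consume them
directly, with a hard (argmax) level exported alongside for inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CovariateSchema, missingness_report  # noqa: F401  (re-export)
from .famd import encode_parts


@dataclass
class ImputationResult:
    """Completed covariate table plus convergence diagnostics.

    ``completed`` holds quantitative cells as reals and categorical
    cells as hard (argmax) levels.  ``fuzzy`` holds category memberships
    for every individual — 0/1 for observed cells, nonnegative and
    summing to one per variable for imputed cells.
    """

    completed: pd.DataFrame
    quantitative: pd.DataFrame
    fuzzy: pd.DataFrame
    fuzzy_var: list[str]
    schema: CovariateSchema | None
    ncp: int
    iterations: int
    final_relative_change: float
    converged: bool
    missing_mask: pd.DataFrame


def _infer_kinds(data: pd.DataFrame, schema: CovariateSchema | None) -> tuple[list[str], list[str]]:
    if schema is not None:
        return (
            [c for c in data.columns if c in schema.quantitative],
            [c for c in data.columns if c in schema.categorical],
        )
    quant = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    return quant, [c for c in data.columns if c not in quant]


def impute_famd(
    data: pd.DataFrame,
    ncp: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    schema: CovariateSchema | None = None,
    seed: int | None = None,
) -> ImputationResult:
    """Impute missing cells of a mixed table by regularized iterative FAMD.

    Parameters
    ----------
    data
        Mixed table with NaN for missing cells; every variable needs at
        least one observed value and no row may be entirely missing.
    ncp
        Number of components for the reconstruction.  ``ncp=0`` degrades
        to plain mean / proportion imputation with no iteration.
    tol
        Convergence threshold on the sum of squared changes in imputed
        cells relative to the previous iteration.
    max_iter
        Iteration cap; non-convergence is flagged, not fatal.
    seed
        Accepted for interface uniformity; the algorithm is
        deterministic (mean/proportion initialization), so it is unused.
    """
    quant_cols, qual_cols = _infer_kinds(data, schema)
    n = len(data)
    if n == 0:
        raise ValueError("empty table")
    fully_missing = data.isna().all(axis=1)
    if fully_missing.any():
        raise ValueError(f"rows entirely missing: {data.index[fully_missing].tolist()}")
    never_observed = data.isna().all(axis=0)
    if never_observed.any():
        raise ValueError(f"variables with no observed value: {data.columns[never_observed].tolist()}")

    missing_mask = data.isna()

    # --- initialize completed blocks -----------------------------------
    Q = data[quant_cols].astype(float).copy() if quant_cols else pd.DataFrame(index=data.index)
    for c in quant_cols:
        Q.loc[missing_mask[c], c] = Q[c].mean(skipna=True)

    fuzzy_parts: list[pd.DataFrame] = []
    fuzzy_var: list[str] = []
    for v in qual_cols:
        col = data[v].astype(object)
        levels = (
            list(schema.levels_of(v))
            if schema is not None
            else sorted({str(x) for x in col.dropna()})
        )
        observed = col.dropna().astype(str)
        props = observed.value_counts(normalize=True).reindex(levels).fillna(0.0)
        block = pd.DataFrame(0.0, index=data.index, columns=[f"{v}={lv}" for lv in levels])
        for lv in levels:
            block.loc[(col.astype(str) == lv) & col.notna(), f"{v}={lv}"] = 1.0
        block.loc[missing_mask[v], :] = props.to_numpy()
        # drop never-observed levels (zero proportion => zero weight undefined)
        keep = [f"{v}={lv}" for lv in levels if props[lv] > 0]
        block = block[keep]
        if block.shape[1] < 2:
            raise ValueError(f"categorical variable {v!r} has fewer than 2 observed levels")
        fuzzy_parts.append(block)
        fuzzy_var.extend([v] * block.shape[1])
    F = pd.concat(fuzzy_parts, axis=1) if fuzzy_parts else pd.DataFrame(index=data.index)

    quant_miss = missing_mask[quant_cols].to_numpy() if quant_cols else np.zeros((n, 0), bool)
    fuzzy_miss = (
        np.column_stack([missing_mask[v].to_numpy() for v in fuzzy_var])
        if fuzzy_var
        else np.zeros((n, 0), bool)
    )

    any_missing = missing_mask.to_numpy().any()
    iterations = 0
    rel_change = 0.0
    converged = True

    if any_missing and ncp > 0:
        converged = False
        for iterations in range(1, max_iter + 1):
            enc = encode_parts(Q, F, fuzzy_var)
            A = enc.X / np.sqrt(n)
            U, s, Vt = np.linalg.svd(A, full_matrices=False)
            lam = s**2
            rank = int(np.sum(s > max(s[0], 1e-300) * 1e-12))
            if ncp >= rank:
                raise ValueError(f"ncp={ncp} must be below the attained rank {rank}")
            sigma2 = float(lam[ncp:rank].mean())
            shrunk = np.maximum(lam[:ncp] - sigma2, 0.0) / s[:ncp]
            Zhat = np.sqrt(n) * (U[:, :ncp] * shrunk) @ Vt[:ncp]

            nq = len(quant_cols)
            old_q = Q.to_numpy(copy=True) if nq else np.zeros((n, 0))
            old_f = F.to_numpy(copy=True) if fuzzy_var else np.zeros((n, 0))

            if nq:
                sds = np.array([enc.quant_sds[c] for c in quant_cols])
                mus = np.array([enc.quant_means[c] for c in quant_cols])
                fitted_q = Zhat[:, :nq] * sds + mus
                newq = Q.to_numpy()
                newq[quant_miss] = fitted_q[quant_miss]
                Q = pd.DataFrame(newq, index=Q.index, columns=quant_cols)
            if fuzzy_var:
                sqp = np.sqrt(enc.col_prop[nq:])
                fitted_f = Zhat[:, nq:] * sqp + sqp**2
                newf = F.to_numpy()
                newf[fuzzy_miss] = fitted_f[fuzzy_miss]
                F = pd.DataFrame(newf, index=F.index, columns=F.columns)

            num = 0.0
            den = 0.0
            if nq:
                num += float(((Q.to_numpy() - old_q)[quant_miss] ** 2).sum())
                den += float((old_q[quant_miss] ** 2).sum())
            if fuzzy_var:
                num += float(((F.to_numpy() - old_f)[fuzzy_miss] ** 2).sum())
                den += float((old_f[fuzzy_miss] ** 2).sum())
            rel_change = num / max(den, 1e-300)
            if rel_change < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"imputation did not converge in {max_iter} iterations "
                f"(relative change {rel_change:.3g})"
            )
    else:  # ncp == 0 (mean/proportion fill, already done) or nothing missing
        iterations = 1

    # final fuzzy memberships: clip tiny negatives, renormalize per variable
    if fuzzy_var:
        Fc = F.clip(lower=0.0)
        var_arr = np.array(fuzzy_var)
        for v in dict.fromkeys(fuzzy_var):
            cols = F.columns[var_arr == v]
            tot = Fc[cols].sum(axis=1)
            Fc.loc[:, cols] = Fc[cols].div(tot.replace(0.0, np.nan), axis=0).fillna(1.0 / len(cols))
        F = Fc

    completed = pd.DataFrame(index=data.index)
    for c in data.columns:
        if c in quant_cols:
            out = data[c].astype(float).copy()
            out[missing_mask[c]] = Q[c][missing_mask[c]]
            completed[c] = out
        else:
            var_arr = np.array(fuzzy_var)
            cols = F.columns[var_arr == c]
            hard = F[cols].idxmax(axis=1).str.split("=", n=1).str[1]
            out = data[c].astype(object).copy()
            out[missing_mask[c]] = hard[missing_mask[c]]
            completed[c] = out.astype(str)

    return ImputationResult(
        completed=completed,
        quantitative=Q,
        fuzzy=F,
        fuzzy_var=fuzzy_var,
        schema=schema,
        ncp=ncp,
        iterations=iterations,
        final_relative_change=rel_change,
        converged=converged,
        missing_mask=missing_mask,
    )


def select_ncp_kfold(
    data: pd.DataFrame,
    candidates: range | list[int] = range(0, 7),
    n_folds: int = 5,
    seed: int = 0,
    schema: CovariateSchema | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[int, pd.DataFrame]:
    """Optional K-fold cell-deletion choice of the number of components.

    Observed quantitative cells are split into folds; each fold is
    masked in turn, imputed at every candidate rank, and scored by the
    mean squared error of the recovered cells.  Returns the best rank
    and the per-candidate score table.  Off the default pipeline path.
    """
    rng = np.random.default_rng(seed)
    quant_cols, _ = _infer_kinds(data, schema)
    if not quant_cols:
        raise ValueError("K-fold selection scores quantitative cells; none present")
    cells = [
        (i, c)
        for c in quant_cols
        for i in range(len(data))
        if not pd.isna(data.iloc[i][c])
    ]
    order = rng.permutation(len(cells))
    folds = np.array_split(order, n_folds)

    scores = []
    for ncp in candidates:
        errs: list[float] = []
        for fold in folds:
            masked = data.copy()
            held = [(cells[k][0], cells[k][1]) for k in fold]
            for i, c in held:
                masked.iloc[i, masked.columns.get_loc(c)] = np.nan
            try:
                res = impute_famd(masked, ncp=ncp, tol=tol, max_iter=max_iter, schema=schema)
            except ValueError:
                errs.append(np.inf)
                continue
            for i, c in held:
                truth = float(data.iloc[i][c])
                errs.append((float(res.quantitative[c].iloc[i]) - truth) ** 2)
        scores.append({"ncp": ncp, "mse": float(np.mean(errs))})
    table = pd.DataFrame(scores)
    best = int(table.loc[table["mse"].idxmin(), "ncp"])
    return best, table
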