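"""Factor analysis of mixed data (FAMD) from its SVD definition.

FAMD is a weighted principal component decomposition of a table mixing
quantitative and categorical variables.  Quantitative columns are
standardized (population sd, n denominator) exactly as in PCA on the
correlation matrix; each category of a qualitative variable enters as an
indicator column divided by the square root of its proportion p_k and
then centered, the weighting used in multiple correspondence analysis
(MCA).  Under this encoding a quantitative variable contributes 1 to the
total inertia and a qualitative variable with K levels contributes
K − 1, so the decomposition degenerates exactly to standardized PCA when
all variables are quantitative and to MCA (indicator-matrix convention,
inertia K − J) when all are categorical.

The public surface follows the model/results idiom: build
:class:`FAMD` from a data frame (or an imputation result carrying fuzzy
category memberships), call :meth:`FAMD.fit`, and read eigenvalues,
coordinates and contributions off the returned :class:`FAMDResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CovariateSchema


@dataclass
class EncodedMatrix:
    """Weighted, centered encoding of a mixed table, with column metadata."""

    X: np.ndarray  # n x C, row weight 1/n implied
    columns: list[str]
    col_var: list[str]  # source variable per column
    col_kind: list[str]  # "quantitative" | "category"
    col_prop: np.ndarray  # category proportion p_k (NaN for quantitative)
    quant_means: dict[str, float]
    quant_sds: dict[str, float]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def total_inertia(self) -> float:
        """Q + sum_j (K_j - 1) for hard indicators; computed from the data."""
        return float(np.sum(self.X**2) / self.n)


def _split_kinds(data: pd.DataFrame, schema: CovariateSchema | None) -> tuple[list[str], list[str]]:
    if schema is not None:
        quant = [c for c in data.columns if c in schema.quantitative]
        qual = [c for c in data.columns if c in schema.categorical]
    else:
        quant = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
        qual = [c for c in data.columns if c not in quant]
    return quant, qual


def encode_mixed(data: pd.DataFrame, schema: CovariateSchema | None = None) -> EncodedMatrix:
    """Encode a complete mixed table (hard category labels) for FAMD.

    Raises for missing cells (impute first), zero-variance quantitative
    columns and single-level categorical columns.
    """
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"missing cells in {bad}; impute before encoding")
    quant, qual = _split_kinds(data, schema)
    n = len(data)

    quant_df = data[quant].astype(float) if quant else pd.DataFrame(index=data.index)
    fuzzy_parts = []
    col_var: list[str] = []
    for v in qual:
        dummies = pd.get_dummies(data[v].astype(str), prefix=v, prefix_sep="=").astype(float)
        if dummies.shape[1] < 2:
            raise ValueError(f"categorical variable {v!r} has a single observed level")
        fuzzy_parts.append(dummies)
        col_var.extend([v] * dummies.shape[1])
    fuzzy = pd.concat(fuzzy_parts, axis=1) if fuzzy_parts else pd.DataFrame(index=data.index)
    return encode_parts(quant_df, fuzzy, col_var)


def encode_parts(
    quant: pd.DataFrame, fuzzy: pd.DataFrame, fuzzy_var: list[str]
) -> EncodedMatrix:
    """Encode from a quantitative block plus a (possibly fuzzy) indicator block.

    ``fuzzy`` holds category memberships in [0, 1] summing to 1 per
    variable per row — hard indicators are the 0/1 special case.  Used
    directly by the iterative imputer, whose intermediate category
    memberships are fractional.
    """
    n = len(quant) if len(quant.columns) else len(fuzzy)
    cols: list[np.ndarray] = []
    names: list[str] = []
    col_var: list[str] = []
    col_kind: list[str] = []
    col_prop: list[float] = []
    quant_means: dict[str, float] = {}
    quant_sds: dict[str, float] = {}

    for c in quant.columns:
        x = quant[c].to_numpy(float)
        mu = x.mean()
        sd = x.std(ddof=0)
        if sd == 0.0:
            raise ValueError(f"quantitative variable {c!r} has zero variance")
        cols.append((x - mu) / sd)
        names.append(c)
        col_var.append(c)
        col_kind.append("quantitative")
        col_prop.append(np.nan)
        quant_means[c] = float(mu)
        quant_sds[c] = float(sd)

    for j, c in enumerate(fuzzy.columns):
        ind = fuzzy[c].to_numpy(float)
        p = ind.mean()
        if p <= 0.0:
            raise ValueError(f"category {c!r} unobserved")
        cols.append(ind / np.sqrt(p) - np.sqrt(p))
        names.append(c)
        col_var.append(fuzzy_var[j])
        col_kind.append("category")
        col_prop.append(float(p))

    if not cols:
        raise ValueError("empty table")
    X = np.column_stack(cols)
    return EncodedMatrix(
        X=X,
        columns=names,
        col_var=col_var,
        col_kind=col_kind,
        col_prop=np.array(col_prop),
        quant_means=quant_means,
        quant_sds=quant_sds,
    )


def _weighted_svd(enc: EncodedMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the row-weighted encoded matrix (1/sqrt(n)) X, signs fixed.

    Each dimension's sign is flipped so its largest-magnitude column
    loading is positive, removing the SVD sign indeterminacy.
    """
    A = enc.X / np.sqrt(enc.n)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    V = Vt.T
    for l in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, l])))
        if V[j, l] < 0:
            U[:, l] *= -1
            V[:, l] *= -1
    return U, s, V


class FAMD:
    """Factor analysis of mixed data on a complete covariate table.

    Parameters
    ----------
    data
        Complete mixed table, one row per individual.  Numeric columns
        are treated as quantitative and the rest as categorical unless a
        :class:`~odontofa.datamodel.CovariateSchema` is given.
    schema
        Optional explicit variable declarations.
    """

    def __init__(self, data: pd.DataFrame, schema: CovariateSchema | None = None):
        self.data = data
        self.schema = schema
        self.index = data.index
        self.encoded = encode_mixed(data, schema)

    @classmethod
    def from_completed(cls, imputation) -> "FAMD":
        """Build from an :class:`~odontofa.impute.ImputationResult`,
        consuming the fuzzy category memberships directly (no hard
        assignment step between imputation and the decomposition)."""
        obj = cls.__new__(cls)
        obj.data = imputation.completed
        obj.schema = imputation.schema
        obj.index = imputation.completed.index
        obj.encoded = encode_parts(
            imputation.quantitative, imputation.fuzzy, imputation.fuzzy_var
        )
        return obj

    def fit(self, n_components: int | None = None) -> "FAMDResults":
        U, s, V = _weighted_svd(self.encoded)
        eig = s**2
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        if n_components is None:
            n_components = rank
        if n_components > rank:
            raise ValueError(f"n_components={n_components} exceeds attained rank {rank}")
        return FAMDResults(
            model=self,
            eigenvalues=eig[:rank],
            _U=U[:, :rank],
            _s=s[:rank],
            _V=V[:, :rank],
            n_components=n_components,
        )


@dataclass
class FAMDResults:
    """Fitted FAMD decomposition: eigenvalues, coordinates, contributions."""

    model: FAMD
    eigenvalues: np.ndarray  # all positive eigenvalues, descending
    _U: np.ndarray = field(repr=False)
    _s: np.ndarray = field(repr=False)
    _V: np.ndarray = field(repr=False)
    n_components: int = 0

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def explained_variance_pct(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.total_inertia

    def _dims(self) -> list[str]:
        return [f"dim{l + 1}" for l in range(self.n_components)]

    @property
    def row_coordinates(self) -> pd.DataFrame:
        """Individual coordinates; dimension l has variance λ_l (n denominator)."""
        n = self.model.encoded.n
        F = np.sqrt(n) * self._U[:, : self.n_components] * self._s[: self.n_components]
        return pd.DataFrame(F, index=self.model.index, columns=self._dims())

    @property
    def column_coordinates(self) -> pd.DataFrame:
        G = self._V[:, : self.n_components] * self._s[: self.n_components]
        return pd.DataFrame(G, index=self.model.encoded.columns, columns=self._dims())

    @property
    def column_contributions_pct(self) -> pd.DataFrame:
        """Percent contribution of each encoded column to each dimension."""
        ctr = 100.0 * self._V[:, : self.n_components] ** 2
        return pd.DataFrame(ctr, index=self.model.encoded.columns, columns=self._dims())

    @property
    def variable_contributions_pct(self) -> pd.DataFrame:
        """Contributions aggregated to source variables (sum over categories)."""
        ctr = self.column_contributions_pct.copy()
        ctr["variable"] = self.model.encoded.col_var
        return ctr.groupby("variable").sum().loc[sorted(set(self.model.encoded.col_var))]

    def squared_loadings(self) -> pd.DataFrame:
        """Squared correlation-style link of each variable with each dimension."""
        enc = self.model.encoded
        lam = self.eigenvalues[: self.n_components]
        out = self.variable_contributions_pct / 100.0
        return out * lam

    def screeplot_data(self) -> pd.DataFrame:
        """Per-dimension percent variance and cumulative percent (all dims)."""
        pct = self.explained_variance_pct
        return pd.DataFrame(
            {
                "dimension": np.arange(1, pct.size + 1),
                "eigenvalue": self.eigenvalues,
                "percent_variance": pct,
                "cumulative_percent": np.cumsum(pct),
            }
        )

    def top_contributors(self, dim: int, k: int = 10, by: str = "variable") -> pd.DataFrame:
        """Top-k contributors to dimension ``dim`` (1-based), descending.

        ``by='variable'`` aggregates category columns to their source
        variable; ``by='column'`` ranks raw encoded columns (individual
        categories).  Ties break alphabetically for determinism; the
        sign of association comes from the column coordinate.
        """
        if not 1 <= dim <= self.n_components:
            raise ValueError(f"dim must be in 1..{self.n_components}")
        col = f"dim{dim}"
        if by == "variable":
            ctr = self.variable_contributions_pct[col]
            frame = pd.DataFrame({"contribution_pct": ctr})
        elif by == "column":
            ctr = self.column_contributions_pct[col]
            frame = pd.DataFrame(
                {"contribution_pct": ctr, "coordinate": self.column_coordinates[col]}
            )
            frame["sign"] = np.sign(frame["coordinate"]).astype(int)
        else:
            raise ValueError("by must be 'variable' or 'column'")
        # alphabetical pre-sort + stable sort => ties broken by name
        frame = frame.sort_index().sort_values(
            "contribution_pct", ascending=False, kind="mergesort"
        )
        return frame.head(k)

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        """Low-rank reconstruction of the row-weighted encoded matrix times sqrt(n)."""
        r = self.n_components if n_components is None else n_components
        A = (self._U[:, :r] * self._s[:r]) @ self._V[:, :r].T
        return np.sqrt(self.model.encoded.n) * A

    def summary(self) -> str:
        lines = ["Factor analysis of mixed data", "=" * 33]
        enc = self.model.encoded
        nq = sum(k == "quantitative" for k in enc.col_kind)
        nvar = len(set(enc.col_var))
        lines.append(f"n individuals:        {enc.n}")
        lines.append(f"variables:            {nvar} ({nq} quantitative, {nvar - nq} categorical)")
        lines.append(f"total inertia:        {self.total_inertia:.4f}")
        lines.append(f"components retained:  {self.n_components}")
        lines.append("")
        lines.append("dim   eigenvalue   % variance   cumulative %")
        cum = 0.0
        for l in range(self.n_components):
            pct = self.explained_variance_pct[l]
            cum += pct
            lines.append(f"{l + 1:>3}   {self.eigenvalues[l]:>10.4f}   {pct:>10.2f}   {cum:>12.2f}")
        return "\n".join(lines)
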