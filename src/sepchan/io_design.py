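"""Intensity-file input, channel design matrices, and contrasts.

Two-colour arrays yield a green and a red log2 intensity for every spot.
The analysis stacks the 2n channel observations per probe into one vector
with a fixed row convention: all green channels (arrays 1..n) first, then
all red channels (arrays 1..n).  The design matrix follows the same
convention, so the M/A transformation matrices act as simple block
operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TwoChannelMatrix",
    "TargetsTable",
    "ChannelDesign",
    "ContrastMatrix",
    "read_two_channel",
    "read_targets",
    "build_channel_design",
    "make_contrasts",
]


class FormatError(ValueError):
    """Raised when an input file does not follow the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violate a model precondition."""


class DesignError(ValueError):
    """Raised for rank-deficient or inconsistent design matrices."""


@dataclass
class TwoChannelMatrix:
    """Background-corrected log2 intensities for both channels.

    Parameters
    ----------
    probes : list of str
        Unique probe identifiers, length G.
    arrays : list of str
        Array identifiers, length n.
    green, red : ndarray of shape (G, n)
        log2 intensities for channel 1 (green) and channel 2 (red).
    """

    probes: list
    arrays: list
    green: np.ndarray
    red: np.ndarray

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.ndim != 2 or self.green.shape != self.red.shape:
            raise ValidationError(
                f"green {self.green.shape} and red {self.red.shape} must be "
                "2-D matrices of identical shape"
            )
        G, n = self.green.shape
        if G < 1 or n < 2:
            raise ValidationError(f"need G >= 1 probes and n >= 2 arrays, got {G}x{n}")
        if len(self.probes) != G or len(self.arrays) != n:
            raise ValidationError("probe/array identifier lengths do not match matrices")
        if len(set(self.probes)) != G:
            raise ValidationError("probe identifiers must be unique")
        for name, mat in (("green", self.green), ("red", self.red)):
            if not np.all(np.isfinite(mat)):
                g, i = np.argwhere(~np.isfinite(mat))[0]
                raise ValidationError(
                    f"non-finite {name} intensity at probe {self.probes[g]!r}, "
                    f"array {self.arrays[i]!r}; missing values are not supported"
                )

    @property
    def n_probes(self) -> int:
        return self.green.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.green.shape[1]


@dataclass
class TargetsTable:
    """Treatment conditions hybridized to each channel of each array.

    ``cy3``/``cy5`` give the condition labels on the green and red channel
    respectively, in array order.
    """

    arrays: list
    cy3: list
    cy5: list
    dye_effect: bool = False

    def __post_init__(self) -> None:
        n = len(self.arrays)
        if len(self.cy3) != n or len(self.cy5) != n:
            raise ValidationError("cy3/cy5 columns must have one entry per array")
        if len(set(self.arrays)) != n:
            raise ValidationError("array identifiers must be unique")
        for lab in list(self.cy3) + list(self.cy5):
            if not str(lab).strip():
                raise ValidationError("empty condition label in targets table")

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)

    @property
    def conditions(self) -> list:
        """Condition labels in first-appearance order (green then red scan)."""
        seen: dict = {}
        for lab in list(self.cy3) + list(self.cy5):
            seen.setdefault(lab, None)
        return list(seen)


@dataclass
class ChannelDesign:
    """2n x p design matrix on the channel-observation scale.

    Rows 1..n are the green channels of arrays 1..n, rows n+1..2n the red
    channels of arrays 1..n.  Full column rank is enforced at construction.
    """

    X: np.ndarray
    coef_names: list
    n_arrays: int
    row_convention: str = "green-then-red"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = self.n_arrays
        if self.X.shape[0] != 2 * n:
            raise DesignError(f"design has {self.X.shape[0]} rows, expected 2n = {2 * n}")
        if self.X.shape[1] != len(self.coef_names):
            raise DesignError("coefficient names do not match design columns")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            aliased = _aliased_columns(self.X, self.coef_names)
            raise DesignError(
                f"design matrix is rank deficient (rank {rank} < {self.X.shape[1]}); "
                f"aliased coefficients: {aliased}"
            )


@dataclass
class ContrastMatrix:
    """p x k matrix of contrast coefficients with contrast names."""

    C: np.ndarray
    names: list
    coef_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.C.shape[1] != len(self.names):
            raise ValidationError("contrast names do not match contrast columns")
        if np.any(np.all(self.C == 0.0, axis=0)):
            raise ValidationError("every contrast column must be nonzero")


def _aliased_columns(X: np.ndarray, names: list) -> list:
    """Columns that do not increase the rank when added left to right."""
    aliased = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            aliased.append(names[j])
        rank = r
    return aliased


def _read_intensity_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no array columns found")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            # astype(float) is correctly rounded, unlike the csv fast path
            vals = df[col].astype(float)
        except (TypeError, ValueError):
            vals = pd.to_numeric(df[col], errors="coerce")
        arr = vals.to_numpy(dtype=float)
        bad = vals.index[~np.isfinite(arr)]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric or missing value at probe {bad[0]!r}, array {col!r}"
            )
        out[col] = vals
    return out


def read_two_channel(path_green, path_red) -> TwoChannelMatrix:
    """Read one TSV per channel (header = array ids, first column = probe ids).

    Arrays and probes are aligned by identifier, so column or row order may
    differ between the two files.
    """
    g = _read_intensity_tsv(path_green)
    r = _read_intensity_tsv(path_red)
    if set(g.index) != set(r.index) or set(g.columns) != set(r.columns):
        raise FormatError("green and red files disagree on probe or array identifiers")
    if g.index.has_duplicates:
        raise ValidationError("duplicate probe identifiers")
    r = r.loc[g.index, g.columns]
    return TwoChannelMatrix(
        probes=list(g.index),
        arrays=list(g.columns),
        green=g.to_numpy(dtype=float),
        red=r.to_numpy(dtype=float),
    )


def write_two_channel(y: TwoChannelMatrix, path_green, path_red) -> None:
    for path, mat in ((path_green, y.green), (path_red, y.red)):
        # %.17g guarantees binary round-trip of doubles through the TSV
        pd.DataFrame(mat, index=y.probes, columns=y.arrays).to_csv(
            path, sep="\t", index_label="Probe", float_format="%.17g"
        )


def read_targets(path) -> TargetsTable:
    """Read a targets TSV with columns Array, Cy3, Cy5 (optional DyeEffect)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"Array", "Cy3", "Cy5"}
    if not required.issubset(df.columns):
        raise FormatError(f"targets file must have columns {sorted(required)}")
    dye = False
    if "DyeEffect" in df.columns:
        dye = df["DyeEffect"].astype(str).str.lower().isin(("1", "true", "yes")).any()
    return TargetsTable(
        arrays=list(df["Array"]),
        cy3=list(df["Cy3"]),
        cy5=list(df["Cy5"]),
        dye_effect=dye,
    )


def write_targets(t: TargetsTable, path) -> None:
    pd.DataFrame({"Array": t.arrays, "Cy3": t.cy3, "Cy5": t.cy5}).to_csv(
        path, sep="\t", index=False
    )


def build_channel_design(
    targets: TargetsTable,
    parameterization: str | np.ndarray = "one_hot_conditions",
    dye_effect: bool | None = None,
) -> ChannelDesign:
    """Build the 2n x p design matrix on channel observations.

    Under ``one_hot_conditions`` each condition gets an indicator column
    (no intercept), so coefficients are population mean log2 intensities per
    condition and comparisons are expressed through contrasts.  A dye effect,
    if requested, adds a column that is 0 for green rows and 1 for red rows.
    A custom 2n x p array may be passed instead.
    """
    n = targets.n_arrays
    if dye_effect is None:
        dye_effect = targets.dye_effect
    if isinstance(parameterization, str):
        if parameterization != "one_hot_conditions":
            raise ValueError(f"unknown parameterization {parameterization!r}")
        conditions = targets.conditions
        p = len(conditions)
        X = np.zeros((2 * n, p))
        idx = {c: j for j, c in enumerate(conditions)}
        for i in range(n):
            X[i, idx[targets.cy3[i]]] = 1.0  # green rows first
            X[n + i, idx[targets.cy5[i]]] = 1.0
        names = list(conditions)
    else:
        X = np.asarray(parameterization, dtype=float)
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    if dye_effect:
        dye = np.concatenate([np.zeros(n), np.ones(n)])
        X = np.column_stack([X, dye])
        names = names + ["Dye"]
    return ChannelDesign(X=X, coef_names=names, n_arrays=n)


def make_contrasts(design: ChannelDesign, spec: list) -> ContrastMatrix:
    """Parse contrast strings like ``"BvsC = B - C"`` into a p x k matrix.

    The right-hand side is a linear combination of coefficient names with
    optional numeric multipliers (``0.5*B``).
    """
    names = []
    cols = []
    coef_idx = {name: j for j, name in enumerate(design.coef_names)}
    for entry in spec:
        if "=" not in entry:
            raise ValueError(f"contrast {entry!r} must have the form 'name = expr'")
        name, expr = (s.strip() for s in entry.split("=", 1))
        if name in names:
            raise ValueError(f"duplicate contrast name {name!r}")
        col = np.zeros(len(design.coef_names))
        for sign, coef, term in _iter_terms(expr):
            if term not in coef_idx:
                raise ValueError(
                    f"unknown coefficient {term!r} in contrast {name!r}; "
                    f"available: {design.coef_names}"
                )
            col[coef_idx[term]] += sign * coef
        names.append(name)
        cols.append(col)
    return ContrastMatrix(
        C=np.column_stack(cols), names=names, coef_names=list(design.coef_names)
    )


def _iter_terms(expr: str):
    """Yield (sign, multiplier, name) triples from '+ 0.5*B - C' style text."""
    import re

    token = re.compile(
        r"\s*([+-]?)\s*(?:(\d+(?:\.\d+)?)\s*\*\s*)?([A-Za-z_][\w.()-]*)"
    )
    pos = 0
    first = True
    while pos < len(expr):
        m = token.match(expr, pos)
        if m is None:
            raise ValueError(f"cannot parse contrast expression at {expr[pos:]!r}")
        sign_s, coef_s, name = m.groups()
        if sign_s == "" and not first:
            raise ValueError(f"missing +/- between terms in {expr!r}")
        sign = -1.0 if sign_s == "-" else 1.0
        coef = float(coef_s) if coef_s else 1.0
        yield sign, coef, name
        pos = m.end()
        first = False
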