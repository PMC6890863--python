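"""Model specification and design/penalty construction.

A model has the shape

    response ~ ordered_factor
               + s(theta)                      reference smooth
               + s(theta, by=ordered_factor)   one difference smooth per
                                               non-reference level
               + s(theta, group, by=...)       random factor smooths

All non-random smooths use the cardinal cubic regression spline basis
with a sum-to-zero constraint over the observed covariate values;
difference smooths are the constrained basis multiplied by the level
indicator (ordered-factor coding).  Random factor smooths get one
unconstrained curve per level of group x by, sharing a wiggliness
smoothing parameter across levels plus a ridge penalty on the penalty
null space so whole curves can shrink to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .basis import CRBasis, cr_basis

__all__ = ["SmoothTermSpec", "ModelSpec", "PenaltyBlock", "DesignInfo", "build_design"]

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class SmoothTermSpec:
    """One smooth term of the model.

    ``is_random`` selects the factor-smooth (per-level random curve)
    construction; for those, ``group`` names the grouping column and
    ``by_factor`` an optional interacting factor column.  Non-random
    terms with a ``by_factor`` are difference smooths relative to the
    factor's first (reference) level.
    """

    covariate: str = "theta"
    k: int = 10
    basis: str = "cr"
    by_factor: str | None = None
    is_random: bool = False
    group: str | None = None
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("k must be >= 4")
        if self.basis != "cr":
            raise ValueError(f"unsupported basis {self.basis!r}")
        if self.penalty_order == 1 and not self.is_random:
            raise ValueError("penalty_order=1 is reserved for random terms")
        if self.is_random and self.group is None:
            raise ValueError("random smooth terms need a grouping column")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a penalized additive mixed model.

    Parameters
    ----------
    response:
        Name of the response column (``rho`` or ``var_rho``).
    factor:
        Name of the ordered parametric factor column, or None for a
        single-condition model.
    factor_levels:
        Level order; first level is the reference.  Defaults to the
        sorted unique values found in the data.
    k:
        Basis dimension for the reference and difference smooths.
    random_terms:
        Sequence of ``(group_column, by_column_or_None)`` pairs, each
        realized as a factor-smooth block.
    ar_phi:
        ``"estimate"`` (two-stage AR(1) estimation), a float in
        ``[0, 1)``, or 0 for independent residuals.
    ar_group:
        Column identifying one contour (AR(1) runs along consecutive
        rows within each group).
    covariate:
        Name of the smooth covariate column.
    """

    response: str = "rho"
    factor: str | None = None
    factor_levels: tuple | None = None
    k: int = 10
    random_terms: tuple = ()
    random_k: int = 10
    ar_phi: object = 0.0
    ar_group: str = "contour_id"
    covariate: str = "theta"

    def __post_init__(self) -> None:
        if isinstance(self.ar_phi, str):
            if self.ar_phi != "estimate":
                raise ValueError("ar_phi must be a float or 'estimate'")
        else:
            phi = float(self.ar_phi)
            if not (0.0 <= phi < 1.0):
                raise ValueError("ar_phi must lie in [0, 1)")
        object.__setattr__(self, "random_terms", tuple(tuple(t) for t in self.random_terms))
        if self.factor_levels is not None:
            object.__setattr__(self, "factor_levels", tuple(self.factor_levels))

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelSpec":
        """Build a spec from a plain dict (YAML-friendly)."""
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        extra = set(cfg) - known
        if extra:
            raise ValueError(f"unknown ModelSpec keys: {sorted(extra)}")
        return cls(**cfg)


@dataclass
class PenaltyBlock:
    """Penalties acting on one contiguous group of design columns.

    The block spans ``n_levels`` repeats of ``bsize`` columns; each
    per-level sub-block is penalized by ``sum_j lambda[idx_j] * mats[j]``.
    """

    name: str
    start: int
    bsize: int
    n_levels: int
    mats: list
    lambda_indices: list
    null_dim_per_level: int
    # precomputed for single-penalty blocks
    _rank: int = 0
    _logdet_pos: float = 0.0

    def __post_init__(self) -> None:
        if len(self.mats) == 1:
            ev = np.linalg.eigvalsh(self.mats[0])
            pos = ev[ev > _EIG_TOL * max(ev.max(), 1.0)]
            self._rank = pos.size
            self._logdet_pos = float(np.sum(np.log(pos)))

    @property
    def size(self) -> int:
        return self.bsize * self.n_levels

    @property
    def null_dim(self) -> int:
        return self.null_dim_per_level * self.n_levels

    def add_to(self, A: np.ndarray, lambdas: np.ndarray) -> None:
        M = sum(lambdas[i] * S for i, S in zip(self.lambda_indices, self.mats))
        for lev in range(self.n_levels):
            sl = slice(self.start + lev * self.bsize, self.start + (lev + 1) * self.bsize)
            A[sl, sl] += M

    def logdet_plus(self, lambdas: np.ndarray) -> float:
        """log of the product of positive eigenvalues of the block penalty."""
        if len(self.mats) == 1:
            lam = lambdas[self.lambda_indices[0]]
            return self.n_levels * (self._rank * np.log(lam) + self._logdet_pos)
        M = sum(lambdas[i] * S for i, S in zip(self.lambda_indices, self.mats))
        if self.null_dim_per_level == 0:
            # structurally full rank: keep every eigenvalue, however small
            # (a numerical cutoff here would erase the log-barrier that
            # penalizes lambda -> 0 and bias selection toward free curves)
            sign, logdet = np.linalg.slogdet(M)
            if sign <= 0:
                return -np.inf
            return self.n_levels * float(logdet)
        ev = np.linalg.eigvalsh(M)
        pos = ev[ev > _EIG_TOL * max(ev.max(), 1.0)]
        return self.n_levels * float(np.sum(np.log(pos)))


@dataclass
class DesignInfo:
    """Design matrix plus everything needed to rebuild rows for new data."""

    X: np.ndarray
    spec: ModelSpec
    basis: CRBasis
    constraint: np.ndarray       # column means of raw basis over training x
    Z: np.ndarray                # k x (k-1) sum-to-zero reparameterization
    factor_levels: tuple
    blocks: list
    n_lambda: int
    col_names: list
    n_unpenalized: int
    term_slices: dict            # name -> slice
    random_info: dict            # term name -> dict(levels=..., start=..., basis=...)
    level_ranges: dict = field(default_factory=dict)  # level -> observed theta (lo, hi)

    @property
    def ncol(self) -> int:
        return self.X.shape[1]

    @property
    def null_space_dim(self) -> int:
        return self.n_unpenalized + sum(b.null_dim for b in self.blocks)

    def constrained_basis(self, x) -> np.ndarray:
        return (self.basis.evaluate(x) - self.constraint) @ self.Z

    def rows(self, newdata: pd.DataFrame, include_random: bool = True) -> np.ndarray:
        """Design rows for new data (same column layout as ``X``)."""
        n = len(newdata)
        M = np.zeros((n, self.ncol))
        M[:, 0] = 1.0
        x = np.asarray(newdata[self.spec.covariate], dtype=float)
        Bc = self.constrained_basis(x)
        levels = self.factor_levels
        if self.spec.factor is not None and len(levels) > 1:
            fac = np.asarray(newdata[self.spec.factor]).astype(str)
            unknown = set(fac) - set(levels)
            if unknown:
                raise ValueError(f"unseen factor level(s): {sorted(unknown)}")
            for j, lev in enumerate(levels[1:]):
                mask = fac == lev
                M[mask, 1 + j] = 1.0
                sl = self.term_slices[f"s(theta):{lev}"]
                M[np.ix_(mask, range(sl.start, sl.stop))] = Bc[mask]
        M[:, self.term_slices["s(theta)"]] = Bc
        if include_random:
            Braw = self.basis.evaluate(x)
            for name, info in self.random_info.items():
                labels = _random_labels(newdata, info["group"], info["by"])
                index = info["index"]
                unseen = set(labels) - set(index)
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {sorted(unseen)} for random term {name}"
                    )
                for lab in set(labels):
                    mask = labels == lab
                    st = info["start"] + index[lab] * info["bsize"]
                    M[np.ix_(mask, range(st, st + info["bsize"]))] = Braw[mask]
        return M


def _random_labels(df: pd.DataFrame, group: str, by: str | None) -> np.ndarray:
    lab = df[group].astype(str)
    if by is not None:
        lab = lab + "\x1f" + df[by].astype(str)
    return lab.to_numpy()


def build_design(spec: ModelSpec, table: pd.DataFrame) -> DesignInfo:
    """Build the dense design matrix and penalty block list for ``spec``.

    Factor levels with zero rows are dropped with a warning.  Column
    order: intercept, parametric contrasts, reference smooth,
    difference smooths (level order), random blocks (term order).
    """
    df = table
    x = np.asarray(df[spec.covariate], dtype=float)
    n = len(df)
    bs = cr_basis(x, spec.k)
    Braw = bs.evaluate(x)
    cmean = Braw.mean(axis=0)

    # sum-to-zero reparameterization: Z spans the null space of cmean
    # (Householder reflection mapping the unit constraint vector onto e1,
    # so columns 2..k of H are orthonormal and orthogonal to the constraint)
    c = cmean / np.linalg.norm(cmean)
    e1 = np.zeros(spec.k)
    e1[0] = 1.0
    v = c - e1
    if np.linalg.norm(v) < 1e-12:
        H = np.eye(spec.k)
    else:
        v = v / np.linalg.norm(v)
        H = np.eye(spec.k) - 2.0 * np.outer(v, v)
    Z = H[:, 1:]
    Bc = (Braw - cmean) @ Z

    levels: tuple
    if spec.factor is not None:
        fac = df[spec.factor].astype(str)
        present = list(pd.unique(fac))
        if spec.factor_levels is not None:
            levels_all = [str(l) for l in spec.factor_levels]
            dropped = [l for l in levels_all if l not in present]
            if dropped:
                warnings.warn(f"dropping factor level(s) with no rows: {dropped}")
            levels = tuple(l for l in levels_all if l in present)
        else:
            levels = tuple(sorted(present))
        fac = fac.to_numpy()
    else:
        levels = ()
        fac = None

    n_contrast = max(len(levels) - 1, 0)
    kc = spec.k - 1  # constrained smooth size

    cols: list[np.ndarray] = [np.ones((n, 1))]
    col_names: list[str] = ["(intercept)"]
    term_slices: dict = {}
    blocks: list[PenaltyBlock] = []
    lam_names: list[str] = []
    pos = 1

    if n_contrast:
        C = np.zeros((n, n_contrast))
        for j, lev in enumerate(levels[1:]):
            C[fac == lev, j] = 1.0
            col_names.append(f"{spec.factor}:{lev}")
        cols.append(C)
        pos += n_contrast

    Sc = Z.T @ bs.penalty @ Z
    Sc = (Sc + Sc.T) / 2.0

    # reference smooth
    cols.append(Bc)
    term_slices["s(theta)"] = slice(pos, pos + kc)
    col_names += [f"s(theta).{j}" for j in range(kc)]
    blocks.append(
        PenaltyBlock("s(theta)", pos, kc, 1, [Sc], [len(lam_names)], null_dim_per_level=1)
    )
    lam_names.append("s(theta)")
    pos += kc

    # difference smooths
    for lev in levels[1:]:
        D = np.zeros((n, kc))
        mask = fac == lev
        D[mask] = Bc[mask]
        cols.append(D)
        name = f"s(theta):{lev}"
        term_slices[name] = slice(pos, pos + kc)
        col_names += [f"{name}.{j}" for j in range(kc)]
        blocks.append(
            PenaltyBlock(name, pos, kc, 1, [Sc], [len(lam_names)], null_dim_per_level=1)
        )
        lam_names.append(name)
        pos += kc

    # random factor-smooth blocks
    random_info: dict = {}
    kr = spec.random_k
    if spec.random_terms:
        bs_r = cr_basis(x, kr) if kr != spec.k else bs
        Br = bs_r.evaluate(x) if kr != spec.k else Braw
        Sr = bs_r.penalty
        Nr = bs_r.null_space()
        Rr = Nr @ Nr.T
        for group, by in spec.random_terms:
            labels = _random_labels(df, group, by)
            uniq = sorted(set(labels))
            index = {lab: i for i, lab in enumerate(uniq)}
            name = f"s(theta,{group}" + (f",{by})" if by else ")")
            G = np.zeros((n, kr * len(uniq)))
            for lab, i in index.items():
                mask = labels == lab
                G[np.ix_(mask, range(i * kr, (i + 1) * kr))] = Br[mask]
            cols.append(G)
            term_slices[name] = slice(pos, pos + kr * len(uniq))
            col_names += [f"{name}[{lab}].{j}" for lab in uniq for j in range(kr)]
            li = len(lam_names)
            blocks.append(
                PenaltyBlock(
                    name, pos, kr, len(uniq), [Sr, Rr], [li, li + 1], null_dim_per_level=0
                )
            )
            lam_names += [f"{name}.wiggle", f"{name}.ridge"]
            random_info[name] = {
                "group": group,
                "by": by,
                "index": index,
                "start": pos,
                "bsize": kr,
            }
            pos += kr * len(uniq)

    level_ranges: dict = {}
    if fac is not None:
        for lev in levels:
            xs = x[fac == lev]
            level_ranges[lev] = (float(xs.min()), float(xs.max()))
    level_ranges[None] = (float(x.min()), float(x.max()))

    X = np.hstack(cols)
    info = DesignInfo(
        X=X,
        spec=spec,
        basis=bs,
        constraint=cmean,
        Z=Z,
        factor_levels=levels,
        blocks=blocks,
        n_lambda=len(lam_names),
        col_names=col_names,
        n_unpenalized=1 + n_contrast,
        term_slices=term_slices,
        random_info=random_info,
        level_ranges=level_ranges,
    )
    # rank check on the unpenalized + fixed-smooth part is deferred to the
    # solver; penalties regularize the rest.
    return info
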