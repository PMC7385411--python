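"""Multivariate analysis of scent composition and ion time series.

Composition differences between species and times of day are analysed with
constrained ordination: Bray-Curtis dissimilarities among square-root
transformed emission profiles are embedded by principal coordinates (PCoA),
and the coordinates are regressed on a design matrix (species, time relative
to sunset, and their interaction).  The fitted variation is eigendecomposed
into canonical (CAP/dbRDA) axes and the residual variation into
unconstrained MDS axes; each model term is tested by a sequential
(Type-I) permutation test on the pseudo-F statistic.

The :class:`CAP` model follows the statsmodels convention: construct from
data, call :meth:`CAP.fit`, and read estimates and tests off the returned
:class:`CAPResults` (``summary()``, :func:`permutation_anova`).

Ion time-series structure is summarised by column-centered PCA and by WPGMA
(McQuitty) hierarchical clustering of Pearson distances among max-scaled
ion traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode

__all__ = [
    "CAP",
    "CAPResults",
    "PCoAResult",
    "bray_curtis",
    "pca_timeseries",
    "pcoa",
    "permutation_anova",
    "wpgma_cluster",
]

_EIG_TOL = 1e-10


def bray_curtis(
    matrix: pd.DataFrame, transform: str = "sqrt"
) -> DistanceMatrix:
    """Bray-Curtis dissimilarities among sample rows.

    ``d(x, y) = sum |x - y| / sum (x + y)`` computed on transformed rows
    (square-root by default, to reduce the skew typical of emission-rate
    data).  Pairs of all-zero rows are assigned distance 0.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a samples x compounds matrix with >= 2 samples")
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative values")
    if transform == "sqrt":
        X = np.sqrt(X)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    condensed = pdist(X, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)  # all-zero pairs
    ids = (
        [str(i) for i in matrix.index]
        if isinstance(matrix, pd.DataFrame)
        else [str(i) for i in range(X.shape[0])]
    )
    return DistanceMatrix(squareform(condensed), ids=ids)


@dataclass
class PCoAResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: np.ndarray  #: n x k, columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  #: positive eigenvalues, descending
    negative_inertia: np.ndarray  #: magnitudes of negative eigenvalues
    ids: list[str] = field(default_factory=list)

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())


def pcoa(distance: DistanceMatrix | np.ndarray) -> PCoAResult:
    """Metric embedding via Gower double-centering and eigendecomposition.

    ``B = -1/2 J D^2 J`` with the centering matrix ``J = I - 11'/n``;
    coordinates are eigenvectors scaled by the square root of their
    (positive) eigenvalues.  Negative eigenvalues — possible because
    Bray-Curtis is not Euclidean — are dropped from the embedding and
    reported as imaginary inertia.
    """
    if isinstance(distance, DistanceMatrix):
        D = distance.data
        ids = list(distance.ids)
    else:
        D = np.asarray(distance, dtype=float)
        ids = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > _EIG_TOL * scale
    neg = eigval < -_EIG_TOL * scale
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return PCoAResult(
        coordinates=coords,
        eigenvalues=eigval[pos],
        negative_inertia=np.abs(eigval[neg]),
        ids=ids,
    )


class CAP:
    """Canonical analysis of principal coordinates (distance-based RDA).

    Parameters
    ----------
    distance : skbio.DistanceMatrix or array
        Dissimilarities among samples (typically Bray-Curtis on square-root
        transformed emission rates).
    design : pandas.DataFrame
        Sample covariates, aligned with the distance-matrix rows.
    formula : str
        Patsy formula over ``design`` columns, e.g.
        ``"species + time_rel_sunset_h + species:time_rel_sunset_h"``.
        The intercept is absorbed by centering.
    features : pandas.DataFrame, optional
        Samples x compounds table used for compound scores; square-root
        transformed when ``transform="sqrt"``.
    """

    def __init__(
        self,
        distance,
        design: pd.DataFrame,
        formula: str,
        features: pd.DataFrame | None = None,
        transform: str = "sqrt",
    ):
        self.distance = distance
        self.design = design.reset_index(drop=True)
        self.formula = formula
        dmat = dmatrix(formula, self.design, return_type="dataframe")
        info = dmat.design_info
        self.term_names = [t for t in info.term_names if t != "Intercept"]
        X = dmat.to_numpy(dtype=float)
        keep = [i for i in range(X.shape[1]) if info.column_names[i] != "Intercept"]
        self._col_names = [info.column_names[i] for i in keep]
        # recompute term slices over the intercept-free matrix
        self._term_cols = {
            t: [keep.index(i) for i in range(*info.term_name_slices[t].indices(X.shape[1])) if i in keep]
            for t in self.term_names
        }
        Xc = X[:, keep]
        Xc = Xc - Xc.mean(axis=0)
        ranks = [np.linalg.matrix_rank(Xc[:, self._term_cols[t]]) for t in self.term_names]
        aliased = [t for t, r in zip(self.term_names, ranks) if r == 0]
        if np.linalg.matrix_rank(Xc) < Xc.shape[1] or aliased:
            bad = aliased or ["(collinear columns)"]
            raise ValueError(f"design matrix rank-deficient; aliased terms: {bad}")
        self.exog = Xc
        if features is not None:
            Z = np.asarray(features, dtype=float)
            if transform == "sqrt":
                Z = np.sqrt(Z)
            self._features = Z
            self._feature_names = list(features.columns)
        else:
            self._features = None
            self._feature_names = []

    @classmethod
    def from_table(cls, table, formula: str, transform: str = "sqrt") -> "CAP":
        """Build from an :class:`~scentdiel.gcms.EmissionTable` (Bray-Curtis
        on transformed rates, design from the sample metadata)."""
        D = bray_curtis(table.rates, transform=transform)
        return cls(D, table.meta, formula, features=table.rates, transform=transform)

    def fit(self) -> "CAPResults":
        emb = pcoa(self.distance)
        Y = emb.coordinates
        n = Y.shape[0]
        # sequential orthonormal bases: Q_j spans terms 1..j
        Qs: list[np.ndarray] = []
        cols: list[int] = []
        for t in self.term_names:
            cols.extend(self._term_cols[t])
            Q, _ = np.linalg.qr(self.exog[:, cols])
            Qs.append(Q)
        Q_full = Qs[-1]
        fitted = Q_full @ (Q_full.T @ Y)
        resid = Y - fitted
        # canonical axes from the fitted values
        Uf, sf, Vtf = np.linalg.svd(fitted, full_matrices=False)
        can_eig = sf**2
        pos = can_eig > _EIG_TOL * max(can_eig.max(initial=0.0), 1.0)
        can_eig = can_eig[pos]
        sample_scores = (Uf * sf)[:, pos]
        # residual (unconstrained MDS) axes
        Ur, sr, _ = np.linalg.svd(resid, full_matrices=False)
        mds_eig = sr**2
        mpos = mds_eig > _EIG_TOL * max(mds_eig.max(initial=0.0), 1.0)
        mds_eig = mds_eig[mpos]
        mds_scores = (Ur * sr)[:, mpos]
        # sequential sums of squares per term
        total = float((Y**2).sum())
        cum = [float(((Q.T @ Y) ** 2).sum()) for Q in Qs]
        ss_terms = np.diff([0.0] + cum)
        ss_res = total - cum[-1]
        df_terms = np.array(
            [len(self._term_cols[t]) for t in self.term_names], dtype=int
        )
        df_res = n - 1 - int(df_terms.sum())
        compound_scores = None
        if self._features is not None and sample_scores.shape[1] > 0:
            Zc = self._features - self._features.mean(axis=0)
            norms = np.linalg.norm(Zc, axis=0)
            norms[norms == 0] = 1.0
            axes = sample_scores / np.linalg.norm(sample_scores, axis=0)
            # weighted correlation of each transformed compound with each axis
            compound_scores = (Zc / norms).T @ axes
        return CAPResults(
            model=self,
            pcoa=emb,
            eigenvalues=can_eig,
            mds_eigenvalues=mds_eig,
            sample_scores=sample_scores,
            mds_scores=mds_scores,
            compound_scores=compound_scores,
            compound_names=self._feature_names,
            ss_terms=ss_terms,
            df_terms=df_terms,
            ss_residual=ss_res,
            df_residual=df_res,
            _Y=Y,
            _Qs=Qs,
        )


@dataclass
class CAPResults:
    """Fitted constrained ordination.

    ``eigenvalues`` are the canonical (constrained) eigenvalues,
    ``mds_eigenvalues`` the residual unconstrained ones; their sum plus the
    imaginary inertia of the PCoA equals the total PCoA inertia.
    """

    model: CAP
    pcoa: PCoAResult
    eigenvalues: np.ndarray
    mds_eigenvalues: np.ndarray
    sample_scores: np.ndarray
    mds_scores: np.ndarray
    compound_scores: np.ndarray | None
    compound_names: list[str]
    ss_terms: np.ndarray
    df_terms: np.ndarray
    ss_residual: float
    df_residual: int
    _Y: np.ndarray
    _Qs: list[np.ndarray]

    @property
    def total_inertia(self) -> float:
        return self.pcoa.total_inertia

    @property
    def constrained_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def constrained_proportion(self) -> float:
        return self.constrained_inertia / self.total_inertia

    def f_statistics(self) -> np.ndarray:
        ms_res = self.ss_residual / self.df_residual
        return (self.ss_terms / self.df_terms) / ms_res

    def anova(self, n_perm: int = 99999, seed: int | None = None) -> pd.DataFrame:
        """Sequential permutation test of each term; see
        :func:`permutation_anova`."""
        return permutation_anova(self, n_perm=n_perm, seed=seed)

    def compound_score_table(self) -> pd.DataFrame:
        if self.compound_scores is None:
            raise ValueError("model was built without a feature table")
        cols = [f"CAP{i + 1}" for i in range(self.compound_scores.shape[1])]
        return pd.DataFrame(self.compound_scores, index=self.compound_names, columns=cols)

    def summary(self, n_perm: int | None = None, seed: int | None = None) -> str:
        lines = [
            "Canonical Analysis of Principal Coordinates (dbRDA)",
            f"  formula: {self.model.formula}",
            f"  samples: {self._Y.shape[0]}",
            f"  total inertia:        {self.total_inertia:.4f}",
            f"  constrained inertia:  {self.constrained_inertia:.4f} "
            f"({100 * self.constrained_proportion:.1f}%)",
            f"  imaginary inertia:    {self.pcoa.negative_inertia.sum():.4f}",
            "",
        ]
        if n_perm:
            tab = self.anova(n_perm=n_perm, seed=seed)
        else:
            tab = pd.DataFrame(
                {
                    "df": np.append(self.df_terms, self.df_residual),
                    "SS": np.append(self.ss_terms, self.ss_residual),
                    "F": np.append(self.f_statistics(), np.nan),
                },
                index=list(self.model.term_names) + ["Residual"],
            )
        lines.append(tab.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of samples on the first two constrained axes (or CAP1
        vs MDS1 for a single-term model)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.sample_scores[:, 0]
        if self.sample_scores.shape[1] > 1:
            y = self.sample_scores[:, 1]
            ax.set_ylabel("CAP2")
        else:
            y = self.mds_scores[:, 0]
            ax.set_ylabel("MDS1")
        ax.scatter(x, y)
        ax.set_xlabel("CAP1")
        return ax


def permutation_anova(
    capfit: CAPResults, n_perm: int = 99999, seed: int | None = None
) -> pd.DataFrame:
    """Sequential (Type-I) permutation test of each CAP model term.

    Rows of the response (PCoA coordinates) are freely permuted; each
    term's pseudo-F is recomputed under every permutation and
    ``p = (exceedances + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = capfit._Y
    n, m = Y.shape
    Qs = capfit._Qs
    sizes = [Q.shape[1] for Q in Qs]
    Q_all = Qs[-1]  # spans all terms; earlier bases are nested prefixes
    total = float((Y**2).sum())
    df_terms = capfit.df_terms
    df_res = capfit.df_residual
    f_obs = capfit.f_statistics()
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(Qs))
    chunk = max(1, min(n_perm, int(2e7 / (n * m + 1))))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((k, n)), axis=1)
        Yp = Y[idx]  # k x n x m
        Z = np.einsum("nk,pnm->pkm", Q_all, Yp)
        Z2 = (Z**2).sum(axis=2)  # k x K columns
        cum = np.cumsum(Z2, axis=1)
        cum_terms = cum[:, np.array(sizes) - 1]  # k x n_terms
        ss_terms = np.diff(np.concatenate([np.zeros((k, 1)), cum_terms], axis=1), axis=1)
        ss_res = total - cum_terms[:, -1]
        f_perm = (ss_terms / df_terms) / (ss_res / df_res)[:, None]
        exceed += (f_perm >= f_obs - 1e-12).sum(axis=0)
        done += k
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "df": np.append(df_terms, df_res),
            "SS": np.append(capfit.ss_terms, capfit.ss_residual),
            "F": np.append(f_obs, np.nan),
            "p": np.append(pvals, np.nan),
        },
        index=list(capfit.model.term_names) + ["Residual"],
    )


def pca_timeseries(
    matrix: pd.DataFrame, threshold: float = 0.001
) -> dict:
    """Column-centered PCA of ion time series (time points x ions).

    Ions whose maximum signal does not exceed ``threshold`` (counts s^-1
    flower^-1) are excluded before the decomposition.  Returns scores for
    time points, loadings for ions, and per-component variance fractions.
    """
    kept = [c for c in matrix.columns if matrix[c].max() > threshold]
    if len(kept) < 2:
        raise ValueError("fewer than 2 ions exceed the signal threshold")
    X = matrix[kept].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    return {
        "ions": kept,
        "scores": U * s,
        "loadings": Vt.T,
        "explained_variance_ratio": var / var.sum(),
    }


@dataclass
class WPGMATree:
    """WPGMA dendrogram over ion time series."""

    linkage: np.ndarray
    labels: list[str]
    distances: np.ndarray
    flagged_constant: list[str]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()


def wpgma_cluster(matrix: pd.DataFrame) -> WPGMATree:
    """WPGMA (McQuitty) clustering of Pearson distances among ion traces.

    Each ion's series (a row of ``matrix``) is scaled to its maximum before
    computing ``d = 1 - r``.  Constant series, for which the correlation is
    undefined, are flagged and placed at the maximal distance 2 from every
    other series.  Labels are sorted lexicographically beforehand so merge
    ties resolve deterministically.
    """
    order = np.argsort(matrix.index.astype(str))
    matrix = matrix.iloc[order]
    labels = [str(i) for i in matrix.index]
    X = matrix.to_numpy(dtype=float)
    maxima = X.max(axis=1)
    if (maxima == 0).any():
        zero = [labels[i] for i in np.nonzero(maxima == 0)[0]]
        raise ValueError(f"ions with zero maximum cannot be scaled: {zero}")
    X = X / maxima[:, None]
    sd = X.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    D = 1.0 - r
    D[constant, :] = 2.0
    D[:, constant] = 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, 2.0)
    Z = linkage(squareform(D, checks=False), method="weighted")
    return WPGMATree(
        linkage=Z,
        labels=labels,
        distances=D,
        flagged_constant=[l for l, c in zip(labels, constant) if c],
    )
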