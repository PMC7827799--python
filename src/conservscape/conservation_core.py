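"""Empirical-Bayes per-site conservation scoring.

The engine behind every conservation number the pipeline reports.  Given a
protein multiple alignment it

1. builds a neighbor-joining guide tree from Kimura-corrected p-distances,
2. estimates (or accepts) a gamma shape for among-site rate variation,
3. computes each column's posterior-mean relative rate under a discrete-gamma
   prior by Felsenstein pruning with an empirical amino-acid model (JTT by
   default), and
4. z-normalises the rates into conservation scores (mean 0, sd 1; lower =
   more conserved) binned into nine grades (9 = most conserved).

Rates are relative: the substitution model is calibrated to one expected
substitution per site per unit branch length at rate 1, and the discrete
gamma prior has mean one, so a posterior rate below 1 means the column
evolves slower than the alignment average.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .io_formats import AMINO_ACIDS, Alignment, PhyloTree, tree_from_newick

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_STATES = 20

#: p-distance above which the Kimura correction is undefined; capped instead
KIMURA_P_MAX = 0.85
KIMURA_D_CAP = 5.2

DEFAULT_K = 16  # discrete gamma categories
ALPHA_BOUNDS = (0.05, 10.0)


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionModel:
    """Time-reversible amino-acid rate matrix calibrated to 1 substitution/site.

    ``Q`` has zero row sums and satisfies detailed balance pi_a Q_ab = pi_b
    Q_ba; the expected rate -sum_a pi_a Q_aa equals one, so branch lengths are
    in expected substitutions per site at relative rate 1.
    """

    Q: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    # eigendecomposition of the pi-symmetrised Q, cached for P(t) = U e^{L t} U^-1
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)

    @classmethod
    def from_exchangeabilities(
        cls, s_lower: Sequence[float], pi: Sequence[float], name: str = "custom"
    ) -> "SubstitutionModel":
        """Build Q from the 190 lower-triangle exchangeabilities and frequencies."""
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ValueError("pi must be 20 positive frequencies")
        pi = pi / pi.sum()
        S = np.zeros((N_STATES, N_STATES))
        idx = 0
        for i in range(1, N_STATES):
            for j in range(i):
                S[i, j] = S[j, i] = s_lower[idx]
                idx += 1
        if idx != len(s_lower):
            raise ValueError(f"expected {idx} exchangeabilities, got {len(s_lower)}")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(pi @ np.diag(Q))  # expected substitutions per unit time
        Q = Q / mu
        # eigendecomposition via the symmetric similarity transform
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2.0)
        U = V / d[:, None]
        Uinv = V.T * d[None, :]
        obj = cls(Q=Q, pi=pi, name=name, _eig=(lam, U, Uinv))
        return obj

    @classmethod
    def jtt(cls) -> "SubstitutionModel":
        """The Jones-Taylor-Thornton (1992) model, the package default."""
        text = resources.files("conservscape.data").joinpath("jtt.txt").read_text()
        numbers: list[float] = []
        for line in text.splitlines():
            if line.startswith("#"):
                continue
            numbers.extend(float(tok) for tok in line.split())
        if len(numbers) != 190 + 20:
            raise ValueError("malformed jtt.txt data file")
        return cls.from_exchangeabilities(numbers[:190], numbers[190:], name="JTT")

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t), clipped to [0, 1] against round-off."""
        lam, U, Uinv = self._eig
        P = (U * np.exp(lam * t)[None, :]) @ Uinv
        return np.clip(P, 0.0, 1.0)


_DEFAULT_MODEL: SubstitutionModel | None = None


def default_model() -> SubstitutionModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = SubstitutionModel.jtt()
    return _DEFAULT_MODEL


# ---------------------------------------------------------------------------
# Discrete gamma prior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaRatePrior:
    """K equiprobable rate categories of a mean-one gamma distribution."""

    alpha: float
    rates: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if abs(r.mean() - 1.0) > 1e-9:
            raise ValueError("category rates must average to one")
        if np.any(np.diff(r) < 0):
            raise ValueError("category rates must be non-decreasing")

    @property
    def K(self) -> int:
        return len(self.rates)


def discretize_gamma(alpha: float, K: int) -> GammaRatePrior:
    """Mean rates of the K equal-probability bins of gamma(alpha, 1/alpha).

    The bin mean follows from the incomplete-gamma identity
    int_a^b x f(x) dx = F_{alpha+1}(alpha b) - F_{alpha+1}(alpha a) for the
    mean-one parameterisation, giving r_k that average exactly to one.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return GammaRatePrior(alpha, np.array([1.0]))
    edges = special.gammaincinv(alpha, np.linspace(0.0, 1.0, K + 1)) / alpha
    upper = special.gammainc(alpha + 1, alpha * edges[1:])
    lower = special.gammainc(alpha + 1, alpha * edges[:-1])
    rates = K * (upper - lower)
    rates = rates / rates.mean()  # absorb residual round-off
    return GammaRatePrior(alpha, rates)


# ---------------------------------------------------------------------------
# Distances and NJ guide tree
# ---------------------------------------------------------------------------

def kimura_protein_distance(seq_a: str, seq_b: str, pair: tuple[str, str] = ("a", "b")) -> float:
    """Kimura-corrected protein distance d = -ln(1 - p - p^2/5).

    ``p`` is the mismatch fraction over mutually non-gap (and non-X) columns.
    Distances for p >= 0.85, where the correction is undefined, are capped.
    """
    n, mismatch = 0, 0
    for ca, cb in zip(seq_a, seq_b):
        if ca in ("-", "X") or cb in ("-", "X"):
            continue
        n += 1
        if ca != cb:
            mismatch += 1
    if n == 0:
        raise ValueError(f"sequences {pair[0]!r} and {pair[1]!r} share no non-gap columns")
    p = mismatch / n
    if p >= KIMURA_P_MAX:
        warnings.warn(
            f"p-distance {p:.3f} between {pair[0]!r} and {pair[1]!r} exceeds "
            f"{KIMURA_P_MAX}; capping distance at {KIMURA_D_CAP}",
            stacklevel=2,
        )
        return KIMURA_D_CAP
    return -math.log(1.0 - p - 0.2 * p * p)


def distance_matrix(alignment: Alignment) -> np.ndarray:
    n = alignment.n_seqs
    D = np.zeros((n, n))
    seqs = [seq for _, seq in alignment.records]
    ids = alignment.ids
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kimura_protein_distance(
                seqs[i], seqs[j], pair=(ids[i], ids[j])
            )
    return D


def nj_tree(D: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Neighbor joining on a distance matrix; negative branch lengths clamped to 0."""
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(ids) == 2:
        d = float(D[0, 1])
        return tree_from_newick(f"({ids[0]}:{d / 2:.10g},{ids[1]}:{d / 2:.10g});")
    dm = DistanceMatrix(D, ids=list(ids))
    sk_tree = _skbio_nj(dm)
    import io as _io

    buf = _io.StringIO()
    sk_tree.write(buf, format="newick")
    tree = tree_from_newick(buf.getvalue())
    for edge in tree.tree.preorder_edge_iter():
        if edge.head_node is tree.tree.seed_node:
            continue
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def build_nj_tree(alignment: Alignment) -> PhyloTree:
    """NJ guide tree from Kimura-corrected pairwise protein distances."""
    if alignment.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    return nj_tree(distance_matrix(alignment), alignment.ids)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _encode_columns(alignment: Alignment, leaf_order: Sequence[str]) -> np.ndarray:
    """(n_leaves, n_cols) state codes; -1 for gap/X (missing data)."""
    codes = np.empty((len(leaf_order), alignment.n_cols), dtype=np.int8)
    for li, sid in enumerate(leaf_order):
        seq = alignment.sequence(sid)
        codes[li] = [AA_INDEX.get(ch, -1) for ch in seq]
    return codes


def _site_log_likelihoods_all(
    codes: np.ndarray, tree: PhyloTree, model: SubstitutionModel, rate: float
) -> np.ndarray:
    """Log-likelihood of every column at a single relative rate.

    Vectorised Felsenstein pruning: one post-order pass computing
    (n_sites, 20) partial arrays per node, with per-site rescaling to avoid
    underflow.  Gap/X leaves contribute all-ones partials.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    n_sites = codes.shape[1]
    leaf_row = {}
    li = 0
    for lf in tree.tree.leaf_node_iter():
        leaf_row[lf] = li
        li += 1
    eye = np.eye(N_STATES)
    partials: dict[object, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            states = codes[leaf_row[node]]
            part = np.ones((n_sites, N_STATES))
            obs = states >= 0
            part[obs] = eye[states[obs]]
            partials[node] = part
        else:
            part = np.ones((n_sites, N_STATES))
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                P = model.transition_matrix(t * rate)
                part = part * (partials.pop(child) @ P.T)
            # rescale per site
            m = part.max(axis=1)
            m[m == 0.0] = 1.0
            part = part / m[:, None]
            log_scale += np.log(m)
            partials[node] = part
    root = tree.tree.seed_node
    site_l = partials[root] @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(site_l) + log_scale


def site_log_likelihood(
    column: str,
    tree: PhyloTree,
    model: SubstitutionModel,
    rate: float,
    leaf_order: Sequence[str] | None = None,
) -> float:
    """Pruning log-likelihood of one alignment column at relative rate ``rate``.

    ``column`` lists one residue per leaf, in ``leaf_order`` (defaults to the
    tree's own leaf iteration order).
    """
    if leaf_order is None:
        leaf_order = tree.leaf_labels
    if len(column) != len(leaf_order):
        raise ValueError("column length does not match number of leaves")
    if set(leaf_order) != set(tree.leaf_labels):
        raise ValueError("leaf order does not match tree leaf labels")
    codes = np.array(
        [[AA_INDEX.get(ch, -1)] for ch in _reorder(column, leaf_order, tree.leaf_labels)],
        dtype=np.int8,
    )
    val = _site_log_likelihoods_all(codes, tree, model, rate)[0]
    if not np.isfinite(val):
        raise ValueError("non-finite site likelihood")
    return float(val)


def _reorder(column: str, given_order: Sequence[str], tree_order: Sequence[str]) -> str:
    by_id = dict(zip(given_order, column))
    return "".join(by_id[sid] for sid in tree_order)


def _loglik_matrix(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel, rates: np.ndarray
) -> np.ndarray:
    """(n_sites, K) matrix of log L_i(r_k)."""
    codes = _encode_columns(alignment, tree.leaf_labels)
    return np.column_stack(
        [_site_log_likelihoods_all(codes, tree, model, float(r)) for r in rates]
    )


# ---------------------------------------------------------------------------
# Gamma shape estimation and posterior rates
# ---------------------------------------------------------------------------

def estimate_alpha(
    alignment: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    K: int = DEFAULT_K,
) -> float:
    """Maximum-likelihood gamma shape under the K-category discrete prior.

    Maximises sum_i log[(1/K) sum_k L_i(r_k)] over log(alpha) in
    [ln 0.05, ln 10] with a bounded scalar search (tolerance 1e-3).  Hitting
    the lower bound (near-invariant data) is flagged with a warning.
    """
    codes = _encode_columns(alignment, tree.leaf_labels)

    def neg_loglik(log_alpha: float) -> float:
        prior = discretize_gamma(math.exp(log_alpha), K)
        ll = np.column_stack(
            [_site_log_likelihoods_all(codes, tree, model, float(r)) for r in prior.rates]
        )
        total = float(np.sum(special.logsumexp(ll, axis=1) - math.log(K)))
        if not np.isfinite(total):
            raise ValueError("non-finite likelihood during alpha estimation")
        return -total

    lo, hi = math.log(ALPHA_BOUNDS[0]), math.log(ALPHA_BOUNDS[1])
    res = optimize.minimize_scalar(
        neg_loglik, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
    )
    alpha_hat = math.exp(res.x)
    if res.x <= lo + 2e-3:
        warnings.warn(
            f"alpha estimate {alpha_hat:.3f} hit the lower search bound; "
            "the alignment may be (nearly) invariant",
            stacklevel=2,
        )
    return float(alpha_hat)


def posterior_mean_rates(
    alignment: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    prior: GammaRatePrior,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes posterior mean rate per column.

    r_hat_i = sum_k r_k w_k L_i(r_k) / sum_k w_k L_i(r_k) with equal prior
    weights w_k = 1/K.  Entirely-gap columns get the prior mean (1.0) and are
    flagged.  Returns ``(rates, all_gap_flags)``.
    """
    tree.validate_against(alignment)
    ll = _loglik_matrix(alignment, tree, model, prior.rates)
    # softmax over categories in log space
    w = np.exp(ll - special.logsumexp(ll, axis=1, keepdims=True))
    rhat = w @ prior.rates
    all_gap = np.array(
        [all(ch in ("-", "X") for ch in alignment.column(i)) for i in range(alignment.n_cols)]
    )
    rhat[all_gap] = 1.0
    if np.any(rhat <= 0) or not np.all(np.isfinite(rhat)):
        raise ValueError("posterior rates must be positive and finite")
    return rhat, all_gap


def normalize_scores(raw_rates: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """z-normalise rates to mean 0, population sd 1 (low score = conserved).

    ``mask`` selects the columns entering the normalisation (e.g. excluding
    all-gap columns); masked-out entries are normalised with the same
    transform but excluded from the moments.
    """
    r = np.asarray(raw_rates, dtype=float)
    sel = np.ones(len(r), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if sel.sum() < 2:
        raise ValueError("need at least 2 scored columns to normalize")
    mu = r[sel].mean()
    sd = r[sel].std()  # population (1/N) standard deviation
    if sd == 0.0:
        raise ValueError("degenerate alignment: zero variance in site rates")
    return (r - mu) / sd


def assign_grades(scores: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Nine equal-count conservation grades; 9 = most conserved (lowest score).

    Quantile binning by rank with ties resolved toward the more-conserved
    grade (tied scores all take the grade of their lowest rank).
    """
    s = np.asarray(scores, dtype=float)
    sel = np.ones(len(s), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    vals = s[sel]
    n = len(vals)
    # min rank = number of strictly smaller values; ties share it
    min_rank = np.searchsorted(np.sort(vals), vals, side="left")
    grades = np.zeros(len(s), dtype=int)
    grades[sel] = 9 - (9 * min_rank) // n
    return grades


# ---------------------------------------------------------------------------
# Score table
# ---------------------------------------------------------------------------

@dataclass
class SiteScoreTable:
    """Per-column conservation results: raw rate, score, grade, coverage."""

    frame: pd.DataFrame  # columns: column, ref_residue, raw_rate, score, grade, coverage

    COLUMNS = ("column", "ref_residue", "raw_rate", "score", "grade", "coverage")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"score table missing columns {missing}")

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy(dtype=float)

    @property
    def raw_rates(self) -> np.ndarray:
        return self.frame["raw_rate"].to_numpy(dtype=float)

    @property
    def grades(self) -> np.ndarray:
        return self.frame["grade"].to_numpy(dtype=int)

    def score_by_residue(self) -> dict[int, float]:
        """Map reference residue number -> normalized score (mapped columns only)."""
        sub = self.frame.dropna(subset=["ref_residue"])
        return {int(r): float(s) for r, s in zip(sub["ref_residue"], sub["score"])}

    def grade_by_residue(self) -> dict[int, int]:
        sub = self.frame.dropna(subset=["ref_residue"])
        return {int(r): int(g) for r, g in zip(sub["ref_residue"], sub["grade"])}

    def write_tsv(self, path: str, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            out = self.frame.copy()
            out["ref_residue"] = out["ref_residue"].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
            out["raw_rate"] = out["raw_rate"].map(lambda v: f"{v:.6f}")
            out["score"] = out["score"].map(lambda v: f"{v:.6f}")
            out["coverage"] = out["coverage"].map(lambda v: f"{v:.4f}")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "SiteScoreTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        frame["ref_residue"] = pd.to_numeric(frame["ref_residue"], errors="coerce")
        return cls(frame)


def score_alignment(
    alignment: Alignment,
    tree: PhyloTree | None = None,
    model: SubstitutionModel | None = None,
    K: int = DEFAULT_K,
    alpha: float | str = "estimate",
) -> SiteScoreTable:
    """Run the full scoring stage: guide tree, prior, posterior rates, scores.

    ``alpha`` is either a fixed gamma shape or ``"estimate"`` (the default),
    in which case the shape is fit by maximum likelihood on the same data.
    Normalisation is computed over columns with nonzero coverage; all-gap
    columns carry the prior-mean rate and grade 0 (unscored).
    """
    model = model or default_model()
    if tree is None:
        tree = build_nj_tree(alignment)
    tree.validate_against(alignment)
    if alpha == "estimate":
        alpha_val = estimate_alpha(alignment, tree, model, K)
    else:
        alpha_val = float(alpha)
    prior = discretize_gamma(alpha_val, K)
    rhat, all_gap = posterior_mean_rates(alignment, tree, model, prior)
    scored = ~all_gap
    scores = normalize_scores(rhat, mask=scored)
    grades = assign_grades(scores, mask=scored)
    n = alignment.n_seqs
    coverage = np.array(
        [
            sum(ch not in ("-", "X") for ch in alignment.column(i)) / n
            for i in range(alignment.n_cols)
        ]
    )
    frame = pd.DataFrame(
        {
            "column": np.arange(1, alignment.n_cols + 1),
            "ref_residue": np.full(alignment.n_cols, np.nan),
            "raw_rate": rhat,
            "score": scores,
            "grade": grades,
            "coverage": coverage,
        }
    )
    frame.loc[all_gap, "score"] = np.nan
    return SiteScoreTable(frame)
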