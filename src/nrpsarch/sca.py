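"""Statistical coupling analysis, binary-approximation variant.

Each alignment column is reduced to a binary indicator of its consensus
residue.  Conservation is the relative entropy D(f, q) of the consensus
frequency f against the background frequency q (natural log), positions
are weighted by phi = dD/df = ln[f(1-q)/(q(1-f))], and the coupling
matrix is |phi_i phi_j cov(x_i, x_j)|.  Significance is assessed against
a column-scramble null that preserves every column's composition, and
sectors are signed eigenvector thresholdings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stats import GAP, LabeledAlignment

DEFAULT_EPSILON = 0.05
DEFAULT_TRIALS = 100
PSEUDOCOUNT = 0.5  # frequency regularizer: f = (count + l) / (n + 2 l)


@dataclass
class SCAConfig:
    epsilon: float = DEFAULT_EPSILON
    n_trials: int = DEFAULT_TRIALS
    seed: int = 0
    pseudocount: float = PSEUDOCOUNT

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_trials < 1:
            raise ValueError("need at least one null trial")


@dataclass
class BinarizedAlignment:
    matrix: np.ndarray  # (n_rows, n_cols) 0/1
    consensus: list[str]  # a_i per column
    f: np.ndarray  # regularized consensus frequency
    q: np.ndarray  # regularized background frequency of a_i
    columns: np.ndarray  # original column indices retained


@dataclass
class Sector:
    mode: int  # 1-based eigenmode index (sorted by descending eigenvalue)
    sign: str  # "+" or "-"
    members: list[int]  # column indices (into the binarized matrix)
    weights: dict[int, float]


@dataclass
class SCAResult:
    binarized: BinarizedAlignment
    phi: np.ndarray
    coupling: np.ndarray
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # column k = mode k+1
    null_max_eigenvalues: np.ndarray | None = None
    null_threshold: float | None = None
    config: SCAConfig = field(default_factory=SCAConfig)


def _regularize(count: float, n: int, lam: float) -> float:
    return (count + lam) / (n + 2 * lam)


def binarize_alignment(aln: LabeledAlignment, *,
                       pseudocount: float = PSEUDOCOUNT
                       ) -> BinarizedAlignment:
    """Binary consensus-indicator matrix plus per-column (a_i, f_i, q_i).

    Consensus ties break alphabetically; all-gap columns are dropped with
    a warning.  Background q_i is the pooled frequency of a_i over the
    whole alignment, regularized like f_i.
    """
    if aln.n_rows < 2 or aln.n_cols < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    n = aln.n_rows
    pooled: dict[str, int] = {}
    total = 0
    for row in aln.rows:
        for c in row:
            if c != GAP:
                pooled[c] = pooled.get(c, 0) + 1
                total += 1
    keep: list[int] = []
    consensus: list[str] = []
    fs: list[float] = []
    qs: list[float] = []
    cols: list[np.ndarray] = []
    for j in range(aln.n_cols):
        col = aln.column(j)
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            warnings.warn(f"column {j + 1} is all-gap; excluded")
            continue
        best = max(counts.values())
        a = sorted(c for c, k in counts.items() if k == best)[0]
        keep.append(j)
        consensus.append(a)
        fs.append(_regularize(counts[a], n, pseudocount))
        qs.append(_regularize(pooled.get(a, 0) / max(total, 1) * n, n,
                              pseudocount))
        cols.append(np.fromiter((1 if c == a else 0 for c in col),
                                dtype=np.int8, count=n))
    return BinarizedAlignment(
        matrix=np.stack(cols, axis=1), consensus=consensus,
        f=np.array(fs), q=np.array(qs), columns=np.array(keep))


def conservation_Di(f: float | np.ndarray, q: float | np.ndarray
                    ) -> float | np.ndarray:
    """Relative entropy D = f ln(f/q) + (1-f) ln((1-f)/(1-q))."""
    f = np.asarray(f, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1) or np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("f and q must lie strictly inside (0, 1)")
    d = f * np.log(f / q) + (1 - f) * np.log((1 - f) / (1 - q))
    return float(d) if d.ndim == 0 else d


def position_weights(f: np.ndarray, q: np.ndarray) -> np.ndarray:
    """phi_i = ln[f(1-q) / (q(1-f))], the derivative of D_i wrt f."""
    return np.log(f * (1 - q) / (q * (1 - f)))


def coupling_matrix(binary: np.ndarray, f: np.ndarray, q: np.ndarray
                    ) -> np.ndarray:
    """C_ij = phi_i phi_j |cov(x_i, x_j)| (population covariance)."""
    phi = position_weights(f, q)
    x = binary.astype(float)
    cov = np.cov(x, rowvar=False, bias=True)
    cov = np.atleast_2d(cov)
    return np.abs(phi[:, None] * phi[None, :] * cov)


def sca_decomposition(aln: LabeledAlignment,
                      config: SCAConfig | None = None,
                      *, with_null: bool = True) -> SCAResult:
    """Full pipeline: binarize, couple, eigen-decompose, null spectrum."""
    config = config or SCAConfig()
    b = binarize_alignment(aln, pseudocount=config.pseudocount)
    phi = position_weights(b.f, b.q)
    C = coupling_matrix(b.matrix, b.f, b.q)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    result = SCAResult(binarized=b, phi=phi, coupling=C,
                       eigenvalues=evals[order], eigenvectors=evecs[:, order],
                       config=config)
    if with_null:
        null = null_spectrum(b, config)
        result.null_max_eigenvalues = null
        result.null_threshold = float(null.max())
    return result


def null_spectrum(binarized: BinarizedAlignment,
                  config: SCAConfig | None = None) -> np.ndarray:
    """Top eigenvalue per column-scramble trial.

    Each trial independently permutes every column across rows, which
    preserves column compositions exactly (so f, q, phi are unchanged)
    while destroying inter-column covariation.
    """
    config = config or SCAConfig()
    rng = np.random.default_rng(config.seed)
    n, m = binarized.matrix.shape
    out = np.empty(config.n_trials)
    for t in range(config.n_trials):
        shuffled = np.empty_like(binarized.matrix)
        for j in range(m):
            shuffled[:, j] = binarized.matrix[rng.permutation(n), j]
        C = coupling_matrix(shuffled, binarized.f, binarized.q)
        out[t] = np.linalg.eigvalsh(C)[-1]
    return out


def extract_sectors(result: SCAResult,
                    mode_assignments: list[tuple[int, str]],
                    epsilon: float | None = None) -> list[Sector]:
    """Signed-threshold sectors for the requested (mode, sign) pairs.

    Mode indices are 1-based into the descending eigen-spectrum.  The
    positive sector of mode k is {i : <i|k> > eps}; the negative sector
    is {i : <i|k> < -eps}.
    """
    eps = result.config.epsilon if epsilon is None else epsilon
    n_modes = len(result.eigenvalues)
    sectors = []
    for mode, sign in mode_assignments:
        if not 1 <= mode <= n_modes:
            raise IndexError(f"mode {mode} out of range 1..{n_modes}")
        vec = result.eigenvectors[:, mode - 1]
        if sign == "+":
            members = np.nonzero(vec > eps)[0]
        elif sign == "-":
            members = np.nonzero(vec < -eps)[0]
        else:
            raise ValueError(f"sign must be '+' or '-', got {sign!r}")
        sectors.append(Sector(mode=mode, sign=sign,
                              members=[int(i) for i in members],
                              weights={int(i): float(vec[i])
                                       for i in members}))
    return sectors


def clean_matrix(result: SCAResult, *, n_top_modes_removed: int = 1,
                 noise_threshold: float | None = None) -> np.ndarray:
    """Reconstruct the coupling matrix from significant modes only.

    The first ``n_top_modes_removed`` modes (global/phylogenetic
    covariation) are dropped; remaining modes are kept when their
    eigenvalue exceeds the noise threshold (defaults to the null-spectrum
    maximum recorded on ``result``).
    """
    if noise_threshold is None:
        noise_threshold = result.null_threshold
    keep = np.ones(len(result.eigenvalues), dtype=bool)
    keep[:n_top_modes_removed] = False
    if noise_threshold is not None:
        keep &= result.eigenvalues > noise_threshold
    V = result.eigenvectors[:, keep]
    lam = result.eigenvalues[keep]
    return (V * lam[None, :]) @ V.T


def augment_with_labels(aln: LabeledAlignment, label: str
                        ) -> tuple[LabeledAlignment, dict]:
    """Append the categorical label as a final alignment column.

    The label column's consensus is its most frequent class and its
    background is the frequency of the least frequent class.  Returns the
    augmented alignment plus the bookkeeping needed to interpret the
    extra column (its index and background frequency).
    """
    if label not in aln.labels:
        raise ValueError(f"label {label!r} missing")
    values = aln.labels[label]
    if any(v in (None, "", "nan") for v in values):
        raise ValueError(f"label {label!r} missing for some rows")
    classes = sorted(set(values))
    if len(classes) < 2:
        raise ValueError(f"label {label!r} has a single class")
    # encode each class as a distinct single character so the column can
    # ride through the standard binarization
    symbols = ("ACDEFGHIKLMNPQRSTVWY"
               "0123456789abcdefghijklmnopqrstuvwxyz")
    if len(classes) > len(symbols):
        raise ValueError("too many label classes to encode")
    enc = {c: symbols[i] for i, c in enumerate(classes)}
    rows = [r + enc[v] for r, v in zip(aln.rows, values)]
    counts = {c: values.count(c) for c in classes}
    least = min(counts.values()) / len(values)
    augmented = LabeledAlignment(ids=list(aln.ids), rows=rows,
                                 labels=dict(aln.labels))
    return augmented, {"label_column": aln.n_cols,  # 0-based index
                       "background": least,
                       "encoding": enc}


def sca_with_label(aln: LabeledAlignment, label: str,
                   config: SCAConfig | None = None, *,
                   with_null: bool = True) -> tuple[SCAResult, dict]:
    """SCA over the alignment augmented with a trailing label column.

    The label column's background is overridden to the least frequent
    class frequency before weights and couplings are computed.
    """
    config = config or SCAConfig()
    augmented, info = augment_with_labels(aln, label)
    b = binarize_alignment(augmented, pseudocount=config.pseudocount)
    idx = np.nonzero(b.columns == info["label_column"])[0]
    if len(idx) == 1:
        n = augmented.n_rows
        b.q[int(idx[0])] = _regularize(info["background"] * n, n,
                                       config.pseudocount)
    phi = position_weights(b.f, b.q)
    C = coupling_matrix(b.matrix, b.f, b.q)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    result = SCAResult(binarized=b, phi=phi, coupling=C,
                       eigenvalues=evals[order], eigenvectors=evecs[:, order],
                       config=config)
    if with_null:
        null = null_spectrum(b, config)
        result.null_max_eigenvalues = null
        result.null_threshold = float(null.max())
    return result, info


def substrate_contributions(result: SCAResult, label_column: int
                            ) -> np.ndarray:
    """|<label column|k>| per mode (1-based order of the spectrum)."""
    idx = np.nonzero(result.binarized.columns == label_column)[0]
    if len(idx) != 1:
        raise ValueError("label column not present in binarized matrix")
    return np.abs(result.eigenvectors[int(idx[0]), :])


def substrate_related_modes(result: SCAResult, label_column: int,
                            threshold: float = 0.05) -> list[int]:
    contrib = substrate_contributions(result, label_column)
    return [int(k + 1) for k in np.nonzero(contrib > threshold)[0]]
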