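"""Condensation-superfamily subtype classification with profile HMMs.

Profiles are either built from the bundled per-subtype reference
alignments or parsed from HMMER3 text files.  Scoring is a full forward
log-odds against an i.i.d. background null, reported in bits.  Bit-exact
agreement with hmmer is not promised (no bias composition corrections);
the contract is rank agreement and the documented confidence threshold,
which is applied to the full-sequence score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ._layouts import AMINO_ACIDS, SUBTYPE_IDS

LOG2 = np.log2
_MINUS_INF = -np.inf

DEFAULT_THRESHOLD = 200.0  # bits

# fixed transition probabilities used when an alignment column carries no
# gap evidence (log2 space)
_T_DEFAULTS = {"mm": 0.95, "mi": 0.03, "md": 0.02,
               "im": 0.70, "ii": 0.30, "dm": 0.70, "dd": 0.30}
_T_NN = LOG2(0.99)
_T_NB = LOG2(0.01)
_T_BM = LOG2(0.90)
_T_BD = LOG2(0.10)
_T_CC = LOG2(0.99)
_T_CT = LOG2(0.01)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class SubtypeModelError(ValueError):
    pass


@dataclass
class ProfileHMM:
    """A lightweight plan7-style profile.

    ``match_log_odds`` holds per-state log2(e/bg); transition arrays are
    log2 probabilities indexed by state (1..K stored at 0..K-1).
    """

    name: str
    match_log_odds: np.ndarray  # (K, 20)
    t: dict[str, np.ndarray]  # each (K,)
    background: np.ndarray  # (20,)

    @property
    def length(self) -> int:
        return self.match_log_odds.shape[0]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_msa(cls, name: str, rows: list[str], *,
                 pseudocount: float = 1.0,
                 background: np.ndarray | None = None,
                 occupancy: float = 0.5) -> "ProfileHMM":
        if len(rows) < 1:
            raise SubtypeModelError("empty alignment")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise SubtypeModelError(
                f"{name}: alignment rows have inconsistent lengths")
        rows = [r.upper() for r in rows]
        n = len(rows)
        cols = [[r[j] for r in rows] for j in range(width)]
        is_match = [sum(c != "-" for c in col) / n >= occupancy
                    for col in cols]
        if background is None:
            background = np.full(20, 1.0 / 20)
        match_cols = [j for j, m in enumerate(is_match) if m]
        K = len(match_cols)
        if K == 0:
            raise SubtypeModelError(f"{name}: no match columns")
        emis = np.full((K, 20), pseudocount)
        for k, j in enumerate(match_cols):
            for c in cols[j]:
                if c in _AA_INDEX:
                    emis[k, _AA_INDEX[c]] += 1.0
        emis /= emis.sum(axis=1, keepdims=True)
        # transition counts along each row's match/delete/insert path
        cnt = {key: np.full(K, 1.0) for key in _T_DEFAULTS}
        for r in rows:
            state, k = "m", 0  # virtual begin treated as match state 0
            for j in range(width):
                if is_match[j]:
                    nxt = "m" if r[j] != "-" else "d"
                    if k > 0:
                        cnt[state + nxt][k - 1] += 1.0
                    state, k = nxt, k + 1
                elif r[j] != "-":
                    if k > 0:
                        if state != "i":
                            cnt[state + "i"][k - 1] += 1.0
                        else:
                            cnt["ii"][k - 1] += 1.0
                        state = "i"
        t = {}
        for pre, keys in (("m", ("mm", "mi", "md")), ("i", ("im", "ii")),
                          ("d", ("dm", "dd"))):
            tot = sum(cnt[k] for k in keys)
            for k in keys:
                t[k] = LOG2(cnt[k] / tot)
        log_odds = LOG2(emis) - LOG2(background)[None, :]
        return cls(name=name, match_log_odds=log_odds, t=t,
                   background=background)

    @classmethod
    def from_probabilities(cls, name: str, match_probs: np.ndarray,
                           transitions: dict[str, np.ndarray],
                           background: np.ndarray) -> "ProfileHMM":
        log_odds = LOG2(match_probs) - LOG2(background)[None, :]
        t = {k: LOG2(np.clip(v, 1e-30, 1.0)) for k, v in transitions.items()}
        return cls(name=name, match_log_odds=log_odds, t=t,
                   background=background)

    # -- scoring -----------------------------------------------------------

    def score(self, sequence: str) -> float:
        """Forward log-odds score of ``sequence`` in bits."""
        return _forward_batch([self], sequence)[0]


def _forward_batch(models: list["ProfileHMM"], sequence: str) -> list[float]:
    """Forward scores (bits) of one sequence against same-length models.

    Delete chains are resolved with a prefix log-sum-exp trick so every
    residue step is a handful of vectorized operations over (G, K).
    """
    seq = [c for c in sequence.upper() if c != "-"]
    if not seq:
        raise SubtypeModelError("empty query")
    K = models[0].length
    if any(m.length != K for m in models):
        raise SubtypeModelError("batch requires equal model lengths")
    G = len(models)
    x = np.array([_AA_INDEX.get(c, -1) for c in seq])
    L = len(seq)
    dtype = np.float32  # ranking-safe; scores agree with float64 to ~1e-3
    emis = np.stack([m.match_log_odds for m in models]).astype(dtype)
    e = np.where(x[None, :, None] >= 0,
                 emis[:, :, np.clip(x, 0, 19)].transpose(0, 2, 1),
                 dtype(0.0))
    tname = ("mm", "mi", "md", "im", "ii", "dm", "dd")
    t = {k: np.stack([m.t[k] for m in models]).astype(dtype)
         for k in tname}  # (G, K)
    tdd_shift = np.concatenate(
        [np.zeros((G, 1), dtype=dtype),
         np.cumsum(t["dd"][:, :-1], axis=1)], axis=1).astype(dtype)
    neg = dtype(-1e30)

    M = np.full((G, K), neg, dtype=dtype)
    I = np.full((G, K), neg, dtype=dtype)
    C = np.full(G, neg, dtype=dtype)
    N = 0.0
    B = N + _T_NB

    def d_chain(m_row: np.ndarray, b: float) -> np.ndarray:
        vals = np.empty((G, K), dtype=dtype)
        vals[:, 0] = b + _T_BD
        if K > 1:
            vals[:, 1:] = m_row[:, :-1] + t["md"][:, :-1]
            u = vals - tdd_shift
            vals = np.logaddexp2.accumulate(u, axis=1) + tdd_shift
        return vals

    D = d_chain(M, B)
    for step in range(L):
        prev_M, prev_I, prev_D, prev_B = M, I, D, B
        stay = np.logaddexp2(
            np.logaddexp2(prev_M[:, :-1] + t["mm"][:, :-1],
                          prev_I[:, :-1] + t["im"][:, :-1]),
            prev_D[:, :-1] + t["dm"][:, :-1])
        M = np.empty((G, K), dtype=dtype)
        M[:, 0] = prev_B + _T_BM
        M[:, 1:] = stay
        M += e[:, step, :]
        I = np.logaddexp2(prev_M + t["mi"], prev_I + t["ii"])
        N = N + _T_NN
        B = N + _T_NB
        D = d_chain(M, B)
        E = np.logaddexp2(M[:, K - 1], D[:, K - 1])
        C = np.logaddexp2(E, C + _T_CC)
    return [float(v) for v in C + _T_CT]


def score_models(models: list["ProfileHMM"], sequence: str
                 ) -> dict[str, float]:
    """Score one sequence against many models, batching equal lengths."""
    by_len: dict[int, list[ProfileHMM]] = {}
    for m in models:
        by_len.setdefault(m.length, []).append(m)
    out: dict[str, float] = {}
    for group in by_len.values():
        for m, s in zip(group, _forward_batch(group, sequence)):
            out[m.name] = s
    return out


@dataclass(frozen=True)
class SubtypeCall:
    query_id: str
    best_subtype: str
    best_score: float
    scores: dict[str, float] = field(hash=False)
    confidence: str = "confident"
    tie: bool = False


def classify_c_domain(query: str, models: list[ProfileHMM],
                      threshold: float = DEFAULT_THRESHOLD, *,
                      query_id: str = "query") -> SubtypeCall:
    """Best-scoring subtype with the documented confidence rule."""
    if not models:
        raise SubtypeModelError("no subtype models supplied")
    scores = score_models(models, query)
    best = max(scores.values())
    winners = sorted(name for name, s in scores.items() if s == best)
    return SubtypeCall(
        query_id=query_id, best_subtype=winners[0], best_score=best,
        scores=scores,
        confidence="confident" if best > threshold else "Low-confidence",
        tie=len(winners) > 1)


def _msa_dir() -> Path:
    return Path(resources.files("nrpsarch") / "data" / "subtype_msas")


def read_aligned_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    ids, rows = [], []
    chunk_id, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if chunk_id is not None:
                    ids.append(chunk_id)
                    rows.append("".join(parts))
                chunk_id, parts = line[1:].split()[0], []
            else:
                parts.append(line)
    if chunk_id is not None:
        ids.append(chunk_id)
        rows.append("".join(parts))
    return ids, rows


def build_subtype_profiles(msas: dict[str, list[str]], *,
                           pseudocount: float = 1.0) -> list[ProfileHMM]:
    """One profile per subtype reference alignment (>= 3 sequences each)."""
    models = []
    for name in sorted(msas):
        rows = msas[name]
        if len(rows) < 3:
            raise SubtypeModelError(f"{name}: need >= 3 aligned sequences")
        models.append(ProfileHMM.from_msa(name, rows,
                                          pseudocount=pseudocount))
    return models


def load_subtype_models(source: str | Path | None = None, *,
                        include_e: bool = False) -> list[ProfileHMM]:
    """Load the default 18-model panel.

    ``source`` may be a directory of per-subtype reference MSAs (the
    bundled default) or a HMMER3 text file holding one profile per
    subtype — vendored profile files take precedence over MSA-built
    models when supplied.  The epimerization-domain model (``E``) is
    available in addition to the 18 condensation subtypes when
    ``include_e`` is set.
    """
    if source is not None and Path(source).is_file():
        from .io import read_hmm_profiles

        wanted = set(SUBTYPE_IDS) | ({"E"} if include_e else set())
        models = [m for m in read_hmm_profiles(source) if m.name in wanted]
        missing = wanted - {m.name for m in models}
        if missing:
            raise SubtypeModelError(
                f"profile file lacks subtypes: {sorted(missing)}")
        return sorted(models, key=lambda m: m.name)
    directory = Path(source) if source is not None else _msa_dir()
    wanted = list(SUBTYPE_IDS) + (["E"] if include_e else [])
    msas = {}
    for name in wanted:
        path = directory / f"{name}.fasta"
        if not path.exists():
            raise SubtypeModelError(f"missing reference MSA for {name}")
        _ids, rows = read_aligned_fasta(path)
        msas[name] = rows
    return build_subtype_profiles(msas)


def pathway_subtype_context(pathway, calls: dict[str, SubtypeCall]
                            ) -> list[dict]:
    """Preceding carrier/E context for every classified C domain.

    ``pathway`` is a list of DomainArchitecture in pathway order; keys of
    ``calls`` are C-domain ids.  The preceding context is the domain type
    immediately before the C domain (``start`` if none).
    """
    archs = sorted(pathway, key=lambda a: a.offset)
    out = []
    for i, arch in enumerate(archs):
        if arch.domain_type != "C":
            continue
        preceded = archs[i - 1].domain_type if i > 0 else "start"
        call = calls.get(arch.domain_id)
        out.append({"domain_id": arch.domain_id,
                    "subtype": call.best_subtype if call else None,
                    "confidence": call.confidence if call else None,
                    "preceded_by": preceded})
    return out
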