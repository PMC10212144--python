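"""Binding-pocket loop-length analysis for adenylation domains.

Five loops span the pocket region between the A3 motif and the conserved
glycine of the G motif, delimited by motif boundaries and two of the ten
binding-pocket code positions (the 4th and 6th).  Loop-length vectors
feed a capped Euclidean distance matrix, average-linkage clustering into
loop groups, profile normalization, and (conditional) entropies of the
specificity-conferring code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._layouts import LOOP_DEFS
from .catalog import MotifCatalog
from .locator import DomainArchitecture, LocatorError, code_query_positions

LOOP_NAMES = [name for name, _l, _r in LOOP_DEFS]
DISTANCE_CAP = 12.0


@dataclass
class LoopVector:
    a_domain_id: str
    lengths: tuple[int, int, int, int, int]
    group: int | None = None
    substrate: str | None = None
    phylum: str | None = None

    def __post_init__(self):
        if len(self.lengths) != 5:
            raise ValueError("loop vector must have exactly five elements")
        if any(v < 0 for v in self.lengths):
            raise ValueError("loop lengths must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)


@dataclass
class CodeRecord:
    a_domain_id: str
    code: str
    mask: tuple[bool, ...]
    substrate: str | None = None
    phylum: str | None = None
    loop_group: int | None = None

    def __post_init__(self):
        if len(self.code) != len(self.mask):
            raise ValueError("code length must match availability mask")


def loop_vector(arch: DomainArchitecture, catalog: MotifCatalog,
                **labels) -> LoopVector:
    """Five inter-anchor loop lengths for one A-domain architecture.

    Each length counts the residues strictly between the two anchors
    (end of the left anchor to start of the right anchor).  Raises
    :class:`LocatorError` naming the first missing anchor.
    """
    if arch.domain_type != "A":
        raise LocatorError("loop vectors are defined for A domains")
    code_pos = code_query_positions(arch, catalog)

    def anchor(nm: str, side: str) -> int:
        if nm == "Gc":  # central glycine of the G motif
            g = arch.motif("G")
            if g is None:
                raise LocatorError("missing anchor: G motif")
            return g.start + catalog.g_center_offset - 1
        if nm.startswith("s"):
            pos = code_pos.get(nm)
            if pos is None:
                raise LocatorError(f"missing anchor: code position {nm}")
            return pos
        m = arch.motif(nm)
        if m is None:
            raise LocatorError(f"missing anchor: motif {nm}")
        return m.end if side == "left" else m.start

    lengths = []
    for _name, left, right in LOOP_DEFS:
        lo = anchor(left, "left")
        hi = anchor(right, "right")
        lengths.append(max(0, hi - lo - 1))
    return LoopVector(a_domain_id=arch.domain_id,
                      lengths=tuple(lengths), **labels)


def loop_distance_matrix(vectors: list[LoopVector],
                         cap: float = DISTANCE_CAP) -> np.ndarray:
    """Capped Euclidean distances d(u,v) = min(||u - v||, cap)."""
    if len(vectors) < 2:
        raise ValueError("need at least two loop vectors")
    X = np.stack([v.as_array() for v in vectors])
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return np.minimum(d, cap)


def cluster_loop_groups(distances: np.ndarray, k: int = 5,
                        method: str = "average") -> np.ndarray:
    """Hierarchical clustering of the (capped) distance matrix.

    Returns group labels 1..k, renumbered by order of first appearance so
    the partition is input-order deterministic.
    """
    n = distances.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(squareform(distances, checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, g in enumerate(raw):
        if g not in remap:
            remap[g] = len(remap) + 1
        out[i] = remap[g]
    return out


def assign_to_groups(new_vectors: list[LoopVector],
                     centroids: np.ndarray) -> list[int | None]:
    """Nearest-centroid group for new A domains; exact ties -> None."""
    out: list[int | None] = []
    for v in new_vectors:
        d = np.sqrt(((centroids - v.as_array()[None, :]) ** 2).sum(axis=1))
        best = d.min()
        winners = np.nonzero(d == best)[0]
        out.append(int(winners[0]) + 1 if len(winners) == 1 else None)
    return out


def normalize_loop_profile(lengths) -> np.ndarray:
    """(L - min + 1) / (mean - min + 1), element-wise over one loop."""
    L = np.asarray(lengths, dtype=float)
    if L.size == 0:
        raise ValueError("empty loop column")
    return (L - L.min() + 1.0) / (L.mean() - L.min() + 1.0)


def _plugin_entropy(values: list[str]) -> float:
    counts = Counter(values)
    total = len(values)
    p = np.array([c / total for c in counts.values()])
    return float(-(p * np.log2(p)).sum())


def code_entropy(records: list[CodeRecord],
                 condition_on: str = "none", *,
                 min_records: int = 3) -> pd.DataFrame:
    """Per-substrate entropy of the code string, optionally conditioned.

    ``condition_on`` is one of ``none``, ``phylum``, ``group`` or
    ``both``.  Conditional entropy is sum_g p(g) H(code | g).  Substrates
    with fewer than ``min_records`` records are reported but flagged.
    """
    if condition_on not in ("none", "phylum", "group", "both"):
        raise ValueError(f"unknown conditioning {condition_on!r}")

    def cond_key(r: CodeRecord):
        if condition_on == "phylum":
            return (r.phylum,)
        if condition_on == "group":
            return (r.loop_group,)
        if condition_on == "both":
            return (r.phylum, r.loop_group)
        return ("all",)

    rows = []
    by_substrate: dict[str, list[CodeRecord]] = {}
    for r in records:
        by_substrate.setdefault(r.substrate or "unknown", []).append(r)
    for substrate in sorted(by_substrate):
        recs = by_substrate[substrate]
        by_group: dict[tuple, list[str]] = {}
        for r in recs:
            by_group.setdefault(cond_key(r), []).append(r.code)
        total = len(recs)
        h = sum((len(codes) / total) * _plugin_entropy(codes)
                for codes in by_group.values())
        rows.append({"substrate": substrate, "condition": condition_on,
                     "entropy_bits": h, "n": total,
                     "flagged_small": total < min_records})
    return pd.DataFrame(rows)
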