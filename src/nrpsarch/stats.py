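"""Descriptive statistics over standardized architectures and alignments.

Covers per-column frequency/gap profiles, conservation scans for
candidate new motifs, mutual information between alignment columns and
categorical labels (bits, plug-in estimator, gaps as a 21st symbol),
intermotif length tables, and pathway organization counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GAP = "-"


@dataclass
class LabeledAlignment:
    ids: list[str]
    rows: list[str]
    labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")
        self.rows = [r.upper() for r in self.rows]
        for name, values in self.labels.items():
            if len(values) != len(self.rows):
                raise ValueError(f"label {name!r} does not cover all rows")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    @classmethod
    def from_records(cls, records: list[tuple[str, str]],
                     labels: pd.DataFrame | None = None
                     ) -> "LabeledAlignment":
        ids = [rid for rid, _ in records]
        rows = [seq for _, seq in records]
        label_dict: dict[str, list[str]] = {}
        if labels is not None:
            for col in labels.columns:
                series = labels[col]
                if all(rid in labels.index for rid in ids):
                    label_dict[col] = [str(series[rid]) for rid in ids]
        return cls(ids=ids, rows=rows, labels=label_dict)


@dataclass
class PositionProfile:
    frequencies: np.ndarray  # (n_cols, 20) over non-gap rows
    top_aa: list[str]
    top_frequency: np.ndarray
    gap_frequency: np.ndarray
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY"

    @property
    def n_cols(self) -> int:
        return len(self.top_aa)


def position_frequencies(aln: LabeledAlignment) -> PositionProfile:
    """Per-column residue frequencies (over non-gap rows) and gap share."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    index = {a: i for i, a in enumerate(alphabet)}
    n, m = aln.n_rows, aln.n_cols
    freqs = np.zeros((m, 20))
    gaps = np.zeros(m)
    top_aa: list[str] = []
    for j in range(m):
        col = aln.column(j)
        n_gap = sum(c not in index for c in col)
        gaps[j] = n_gap / n
        non_gap = n - n_gap
        for c in col:
            if c in index:
                freqs[j, index[c]] += 1
        if non_gap:
            freqs[j] /= non_gap
        order = np.argsort(-freqs[j], kind="stable")
        top_aa.append(alphabet[order[0]] if non_gap else GAP)
    top_frequency = freqs.max(axis=1)
    return PositionProfile(frequencies=freqs, top_aa=top_aa,
                           top_frequency=top_frequency, gap_frequency=gaps)


def conservation_scan(profile: PositionProfile,
                      motif_spans: list[tuple[int, int]], *,
                      threshold: float = 0.95,
                      min_distance: int = 5) -> list[tuple[int, int]]:
    """Contiguous runs of highly conserved columns away from known motifs.

    ``motif_spans`` are 1-based inclusive column spans of catalog motifs
    in alignment coordinates; returned candidate regions are 1-based
    inclusive column spans as well.
    """
    m = profile.n_cols
    near = np.zeros(m, dtype=bool)
    for start, end in motif_spans:
        lo = max(1, start - min_distance)
        hi = min(m, end + min_distance)
        near[lo - 1:hi] = True
    hot = (profile.top_frequency >= threshold) & ~near
    regions: list[tuple[int, int]] = []
    j = 0
    while j < m:
        if hot[j]:
            k = j
            while k + 1 < m and hot[k + 1]:
                k += 1
            regions.append((j + 1, k + 1))
            j = k + 1
        else:
            j += 1
    return regions


def _entropy(counts: Counter, total: int) -> float:
    if total == 0:
        return 0.0
    p = np.array([c / total for c in counts.values()])
    return float(-(p * np.log2(p)).sum())


def mutual_information(aln: LabeledAlignment, label: str, *,
                       treat_gap_as_symbol: bool = True) -> np.ndarray:
    """MI(column; label) in bits per column, plug-in estimator.

    MI(i) = H(column i) - sum_s p(s) H(column i | label = s).  Gaps are a
    21st symbol by default.
    """
    if label not in aln.labels:
        raise ValueError(f"label {label!r} not present")
    values = aln.labels[label]
    classes = sorted(set(values))
    if len(classes) < 2:
        warnings.warn(f"label {label!r} has a single class; MI is zero")
        return np.zeros(aln.n_cols)
    n = aln.n_rows
    out = np.zeros(aln.n_cols)
    by_class = {s: [i for i, v in enumerate(values) if v == s]
                for s in classes}
    for j in range(aln.n_cols):
        col = aln.column(j)
        if not treat_gap_as_symbol:
            keep = [i for i, c in enumerate(col) if c != GAP]
        else:
            keep = list(range(n))
        if not keep:
            continue
        h_col = _entropy(Counter(col[i] for i in keep), len(keep))
        cond = 0.0
        for s, idx in by_class.items():
            idx = [i for i in idx if i in set(keep)] if not \
                treat_gap_as_symbol else idx
            if not idx:
                continue
            cond += (len(idx) / len(keep)) * _entropy(
                Counter(col[i] for i in idx), len(idx))
        out[j] = max(0.0, h_col - cond)
    return out


def intermotif_length_stats(archs, group_by: dict[str, str] | None = None,
                            boundary_mode: str = "span") -> pd.DataFrame:
    """Per intermotif segment (and optional group): count/median/mean/SD.

    ``group_by`` maps domain ids to a group label (e.g. subtype or
    kingdom); ungrouped domains fall into group ``all``.  With
    ``boundary_mode="anchored"`` segments ending at a motif with a
    defined anchor residue extend up to (but excluding) that anchor, so
    lengths are comparable across subtypes whose motif spans differ.
    """
    from ._layouts import INTERMOTIF_ANCHOR_EXTENSIONS

    if boundary_mode not in ("span", "anchored"):
        raise ValueError(f"unknown boundary mode {boundary_mode!r}")
    rows = []
    for arch in archs:
        group = (group_by or {}).get(arch.domain_id, "all")
        for seg in arch.intermotifs:
            length = seg.length
            if boundary_mode == "anchored":
                length += INTERMOTIF_ANCHOR_EXTENSIONS.get(
                    seg.following_motif, 0)
            rows.append({"segment_id": seg.segment_id, "group": group,
                         "length": length})
    if not rows:
        return pd.DataFrame(columns=["segment_id", "group", "count",
                                     "median", "mean", "sd"])
    df = pd.DataFrame(rows)
    out = []
    for (seg, group), sub in df.groupby(["segment_id", "group"]):
        lengths = sub["length"].to_numpy(dtype=float)
        out.append({
            "segment_id": seg, "group": group, "count": len(lengths),
            "median": float(np.median(lengths)),
            "mean": float(np.mean(lengths)),
            "sd": float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0,
            "sd_defined": len(lengths) > 1,
            "histogram": dict(Counter(int(v) for v in lengths)),
        })
    return pd.DataFrame(out)


def pathway_organization(pathways: list[tuple[str, list]],
                         calls: dict[str, "object"] | None = None, *,
                         require_confident_c: bool = True) -> pd.DataFrame:
    """Frequency table of canonical pathway organization strings.

    ``pathways`` is a list of (pathway_id, ordered DomainArchitecture
    list); ``calls`` maps C-domain ids to SubtypeCall.  Each pathway
    becomes a string of ordered domain types with C subtypes substituted,
    e.g. ``C(LCL)-A-T-TE``.  Pathways containing a Low-confidence C
    domain are excluded when ``require_confident_c`` is set.
    """
    calls = calls or {}
    org_strings = []
    for pid, archs in pathways:
        parts = []
        excluded = False
        for arch in sorted(archs, key=lambda a: a.offset):
            if arch.domain_type == "C":
                call = calls.get(arch.domain_id)
                if call is None or call.confidence != "confident":
                    if require_confident_c:
                        excluded = True
                        break
                    parts.append("C(Low-confidence)")
                else:
                    parts.append(f"C({call.best_subtype})")
            else:
                parts.append(arch.domain_type)
        if not excluded:
            org_strings.append("-".join(parts))
    counts = Counter(org_strings)
    total = sum(counts.values())
    rows = [{"organization": org, "count": c,
             "fraction": c / total if total else 0.0}
            for org, c in counts.most_common()]
    return pd.DataFrame(rows, columns=["organization", "count", "fraction"])
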