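"""Motif location and standardized motif/intermotif partitioning.

Queries are aligned globally against candidate reference domains; the
best-scoring reference wins and its curated motif spans are transferred
to query coordinates through the alignment.  The residues strictly
between consecutive motifs become the intermotif segments, so motifs and
intermotifs tile the covered region of the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import PairwiseAlignment, global_align
from .catalog import MotifCatalog, ReferenceDomain

# exclusive module-length windows (pattern -> (low, high))
MODULE_WINDOWS = {
    "C+A+T": (1000, 1300),
    "C+A+T+C": (1500, 1750),
    "C+A+T+E": (1350, 2350),
}


class LocatorError(ValueError):
    pass


@dataclass(frozen=True)
class MotifAnnotation:
    motif_id: str
    start: int  # 1-based inclusive on the query
    end: int
    observed_sequence: str
    standard_length_flag: bool
    optional: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IntermotifSegment:
    preceding_motif: str
    following_motif: str
    start: int
    end: int  # end = start - 1 encodes an empty segment

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def segment_id(self) -> str:
        return f"{self.preceding_motif}-{self.following_motif}"


@dataclass
class DomainArchitecture:
    domain_id: str
    domain_type: str
    subtype: str
    reference_id: str
    sequence: str
    motifs: list[MotifAnnotation]
    intermotifs: list[IntermotifSegment]
    score: float
    truncated: bool = False
    dead_domain: bool = False
    offset: int = 1  # 1-based start of this domain on its parent protein
    ref_query_map: dict[int, int] = field(default_factory=dict, repr=False)

    def motif(self, motif_id: str) -> MotifAnnotation | None:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        return None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_rows(self) -> list[dict]:
        rows = []
        segs: list[tuple[int, str, str, int, int, str]] = []
        for m in self.motifs:
            segs.append((m.start, "motif", m.motif_id, m.end,
                         int(m.standard_length_flag), m.observed_sequence))
        for s in self.intermotifs:
            if s.length > 0:
                segs.append((s.start, "intermotif", s.segment_id, s.end, 1,
                             self.sequence[s.start - 1:s.end]))
        for start, kind, sid, end, flag, obs in sorted(segs):
            rows.append({
                "sequence_id": self.domain_id,
                "domain_type": self.domain_type,
                "subtype": self.subtype,
                "segment_kind": kind,
                "segment_id": sid,
                "start": start,
                "end": end,
                "length": end - start + 1,
                "observed_sequence": obs,
                "standard_length": flag,
                "truncated": int(self.truncated),
                "dead_domain": int(self.dead_domain),
            })
        return rows

    def to_dict(self) -> dict:
        return {
            "domain_id": self.domain_id,
            "domain_type": self.domain_type,
            "subtype": self.subtype,
            "reference_id": self.reference_id,
            "score": self.score,
            "truncated": self.truncated,
            "dead_domain": self.dead_domain,
            "motifs": [{"motif_id": m.motif_id, "start": m.start,
                        "end": m.end, "length": m.length,
                        "observed_sequence": m.observed_sequence,
                        "standard_length": m.standard_length_flag,
                        "optional": m.optional} for m in self.motifs],
            "intermotifs": [{"segment_id": s.segment_id, "start": s.start,
                             "end": s.end, "length": s.length}
                            for s in self.intermotifs],
        }


def locate_motifs(query: str, references: list[ReferenceDomain],
                  catalog: MotifCatalog, *,
                  query_id: str = "query") -> DomainArchitecture:
    """Parse one domain sequence into its motif/intermotif architecture."""
    if not query:
        raise LocatorError("empty query sequence")
    if not references:
        raise LocatorError("no reference domains supplied")
    dtypes = {r.domain_type for r in references}
    if len(dtypes) > 1:
        raise LocatorError(f"references mix domain types: {sorted(dtypes)}")
    query = query.upper()
    best: tuple[PairwiseAlignment, ReferenceDomain] | None = None
    for ref in sorted(references, key=lambda r: r.id):
        aln = global_align(query, ref.sequence, query_id=query_id,
                           reference_id=ref.id)
        if best is None or aln.score > best[0].score:
            best = (aln, ref)
    aln, ref = best
    rmap = aln.reference_to_query_map()

    effective = {m.motif_id: m for m in
                 catalog.motifs_for(ref.domain_type, ref.subtype)}
    motifs: list[MotifAnnotation] = []
    truncated = False
    for motif_id, rstart, rend in ref.motif_spans:
        mdef = effective.get(motif_id)
        mapped = [rmap[p] for p in range(rstart, rend + 1) if p in rmap]
        if not mapped:
            if mdef is None or not mdef.optional:
                truncated = True
            continue
        qstart, qend = min(mapped), max(mapped)
        fully = len(mapped) == rend - rstart + 1
        length = qend - qstart + 1
        standard = (fully and mdef is not None
                    and length == mdef.prevalent_length)
        motifs.append(MotifAnnotation(
            motif_id=motif_id, start=qstart, end=qend,
            observed_sequence=query[qstart - 1:qend],
            standard_length_flag=standard,
            optional=bool(mdef and mdef.optional)))
    motifs.sort(key=lambda m: m.start)

    intermotifs = [
        IntermotifSegment(preceding_motif=a.motif_id,
                          following_motif=b.motif_id,
                          start=a.end + 1, end=b.start - 1)
        for a, b in zip(motifs, motifs[1:])
    ]
    core_ids = set(catalog.core_motif_ids(ref.domain_type))
    present = {m.motif_id for m in motifs}
    arch = DomainArchitecture(
        domain_id=query_id, domain_type=ref.domain_type, subtype=ref.subtype,
        reference_id=ref.id, sequence=query, motifs=motifs,
        intermotifs=intermotifs, score=aln.score, truncated=truncated,
        ref_query_map=rmap)
    arch.dead_domain = not _passes_dead_filter(arch, core_ids, present)
    return arch


def _passes_dead_filter(arch: DomainArchitecture, core_ids: set[str],
                        present: set[str]) -> bool:
    if core_ids - present:
        return False
    return all(m.standard_length_flag for m in arch.motifs)


def dead_domain_filter(arch: DomainArchitecture,
                       catalog: MotifCatalog) -> bool:
    """True iff all core motifs are present at their prevalent lengths."""
    core_ids = set(catalog.core_motif_ids(arch.domain_type))
    present = {m.motif_id for m in arch.motifs}
    return _passes_dead_filter(arch, core_ids, present)


def deduplicate(records: list[tuple[str, str]],
                max_identity: float) -> list[tuple[str, str]]:
    """Greedy removal of near-identical sequences.

    Identity is measured as identical columns over alignment length of
    the global alignment against every already-kept record; a record is
    dropped when its identity to any kept one exceeds ``max_identity``.
    The threshold is a required parameter — no default is claimed.
    """
    if not 0.0 < max_identity <= 1.0:
        raise ValueError("max_identity must be in (0, 1]")
    kept: list[tuple[str, str]] = []
    for rid, seq in records:
        redundant = False
        for _kid, kseq in kept:
            aln = global_align(seq, kseq)
            same = sum(a == b and a != "-" for a, b in
                       zip(aln.aligned_query, aln.aligned_reference))
            if same / len(aln.aligned_query) > max_identity:
                redundant = True
                break
        if not redundant:
            kept.append((rid, seq))
    return kept


@dataclass(frozen=True)
class Module:
    pattern: str
    domain_ids: tuple[str, ...]
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def assemble_modules(pathway: list[DomainArchitecture],
                     windows: dict[str, tuple[int, int]] | None = None
                     ) -> list[Module]:
    """Group consecutive domains into C+A+T(+C/+E) modules.

    Domains must carry pathway order through their ``offset`` fields.
    Only modules whose sequence span falls strictly inside the configured
    length window are retained; other domains pass through unmodularized.
    """
    windows = windows or MODULE_WINDOWS
    archs = sorted(pathway, key=lambda a: a.offset)
    types = [a.domain_type for a in archs]
    out: list[Module] = []
    for i in range(len(archs) - 2):
        if types[i:i + 3] != ["C", "A", "T"]:
            continue
        candidates = [("C+A+T", archs[i:i + 3])]
        if i + 3 < len(archs) and types[i + 3] in ("C", "E"):
            candidates.append((f"C+A+T+{types[i + 3]}", archs[i:i + 4]))
        for pattern, doms in candidates:
            if pattern not in windows:
                continue
            start = doms[0].offset
            end = doms[-1].offset + doms[-1].length - 1
            low, high = windows[pattern]
            if low < end - start + 1 < high:
                out.append(Module(pattern=pattern,
                                  domain_ids=tuple(d.domain_id for d in doms),
                                  start=start, end=end))
    return out


def extract_stachelhaus_code(a_domain: DomainArchitecture,
                             catalog: MotifCatalog
                             ) -> tuple[str, list[bool]]:
    """Residues aligned to the ten binding-pocket code positions.

    Returns the ten-character code (``-`` where a position is not covered
    by the query) and a per-position availability mask.
    """
    if a_domain.domain_type != "A":
        raise LocatorError("specificity code extraction requires an A domain")
    pocket = {"A3", "A4", "A5", "A6"}
    present = {m.motif_id for m in a_domain.motifs}
    if not pocket <= present:
        missing = sorted(pocket - present)
        raise LocatorError(f"query lacks the A3-A6 pocket region: "
                           f"missing {missing}")
    ref = catalog.reference(catalog.code_reference)
    if a_domain.reference_id == ref.id and a_domain.ref_query_map:
        rmap = a_domain.ref_query_map
    else:
        rmap = global_align(a_domain.sequence, ref.sequence,
                            query_id=a_domain.domain_id,
                            reference_id=ref.id).reference_to_query_map()
    code: list[str] = []
    mask: list[bool] = []
    for cid in sorted(catalog.code_positions, key=lambda c: int(c[1:])):
        qpos = rmap.get(catalog.code_positions[cid])
        if qpos is None:
            code.append("-")
            mask.append(False)
        else:
            code.append(a_domain.sequence[qpos - 1])
            mask.append(True)
    return "".join(code), mask


def code_query_positions(a_domain: DomainArchitecture,
                         catalog: MotifCatalog) -> dict[str, int | None]:
    """Query coordinates of the ten code positions (None if uncovered)."""
    ref = catalog.reference(catalog.code_reference)
    if a_domain.reference_id == ref.id and a_domain.ref_query_map:
        rmap = a_domain.ref_query_map
    else:
        rmap = global_align(a_domain.sequence, ref.sequence,
                            query_id=a_domain.domain_id,
                            reference_id=ref.id).reference_to_query_map()
    return {cid: rmap.get(pos)
            for cid, pos in catalog.code_positions.items()}
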