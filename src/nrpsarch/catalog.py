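"""Curated catalog of core motifs and reference domain sequences.

The catalog ties together three bundled data files:

``motifs.tsv``
    one row per motif definition (domain type, subtype scope, reference
    span, consensus pattern, prevalent length, optional flag);
``references.fasta``
    reference domain sequences with ``id|domain_type|subtype`` headers;
``reference_spans.tsv``
    the manually annotated motif spans on every reference;
``code_positions.json``
    the ten binding-pocket code positions on the A-domain reference.

All downstream parsing (the locator, the loop analysis) is anchored on
these data.  Loading validates every self-consistency invariant and
raises :class:`CatalogError` naming the offending motif otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import _layouts
from ._layouts import matches_consensus, consensus_length

DOMAIN_TYPES = ("C", "A", "T", "E", "TE", "ACP")


class CatalogError(ValueError):
    """Raised when catalog data violates a self-consistency invariant."""


@dataclass(frozen=True)
class MotifDefinition:
    domain_type: str
    motif_id: str
    subtype_scope: str  # subtype id or "all"
    start: int  # 1-based inclusive on the scope's reference domain
    end: int
    consensus: str
    prevalent_length: int
    optional: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise CatalogError(
                f"motif {self.motif_id}: malformed span {self.start}..{self.end}")
        if self.prevalent_length != self.end - self.start + 1:
            raise CatalogError(
                f"motif {self.motif_id}: prevalent_length "
                f"{self.prevalent_length} != span length")
        if consensus_length(self.consensus) != self.prevalent_length:
            raise CatalogError(
                f"motif {self.motif_id}: consensus {self.consensus!r} length "
                f"!= prevalent_length {self.prevalent_length}")


@dataclass(frozen=True)
class ReferenceDomain:
    id: str
    domain_type: str
    subtype: str  # subtype id or "canonical"
    sequence: str
    motif_spans: tuple[tuple[str, int, int], ...]  # (motif_id, start, end)


@dataclass
class MotifCatalog:
    motifs: list[MotifDefinition]
    references: dict[str, ReferenceDomain]
    code_reference: str = ""
    code_positions: dict[str, int] = field(default_factory=dict)
    g_center_offset: int = _layouts.G_MOTIF_CENTER
    version: str = "1"

    # -- accessors ---------------------------------------------------------

    def motifs_for(self, domain_type: str, subtype: str = "canonical",
                   include_optional: bool = True) -> list[MotifDefinition]:
        """Catalog order motif definitions effective for one subtype.

        Subtype-scoped rows override same-id rows of scope ``all``.
        """
        base = [m for m in self.motifs
                if m.domain_type == domain_type and m.subtype_scope == "all"]
        overrides = {m.motif_id: m for m in self.motifs
                     if m.domain_type == domain_type
                     and m.subtype_scope == subtype}
        out = [overrides.get(m.motif_id, m) for m in base]
        if not include_optional:
            out = [m for m in out if not m.optional]
        return out

    def core_motif_ids(self, domain_type: str) -> list[str]:
        return [m.motif_id for m in
                self.motifs_for(domain_type, include_optional=False)]

    def references_for(self, domain_type: str) -> list[ReferenceDomain]:
        return [r for r in self.references.values()
                if r.domain_type == domain_type]

    def reference(self, ref_id: str) -> ReferenceDomain:
        return self.references[ref_id]

    def consensus_for(self, domain_type: str, motif_id: str,
                      subtype: str = "canonical") -> str:
        for m in self.motifs_for(domain_type, subtype):
            if m.motif_id == motif_id:
                return m.consensus
        raise KeyError((domain_type, subtype, motif_id))

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for m in self.motifs:
            key = (m.domain_type, m.subtype_scope, m.motif_id)
            if key in seen:
                raise CatalogError(f"duplicate motif {m.motif_id} in scope "
                                   f"{m.domain_type}/{m.subtype_scope}")
            seen.add(key)
        # spans disjoint and strictly ordered within a scope
        by_scope: dict[tuple[str, str], list[MotifDefinition]] = {}
        for m in self.motifs:
            by_scope.setdefault((m.domain_type, m.subtype_scope), []).append(m)
        for (dtype, scope), defs in by_scope.items():
            if scope != "all":
                # overrides are positioned against the full layout
                defs = self.motifs_for(dtype, scope)
            prev_end, prev_id = 0, None
            for m in sorted(defs, key=lambda d: d.start):
                if m.start <= prev_end:
                    raise CatalogError(
                        f"motif {m.motif_id} overlaps {prev_id} in scope "
                        f"{dtype}/{scope}")
                prev_end, prev_id = m.end, m.motif_id
        # reference sequences honour their annotated spans
        for ref in self.references.values():
            for motif_id, start, end in ref.motif_spans:
                if not (1 <= start <= end <= len(ref.sequence)):
                    raise CatalogError(
                        f"motif {motif_id} span {start}..{end} outside "
                        f"reference {ref.id}")
                sub = ref.sequence[start - 1:end]
                subtype = ref.subtype if ref.subtype != "canonical" else "canonical"
                consensus = self.consensus_for(ref.domain_type, motif_id, subtype)
                if not matches_consensus(sub, consensus):
                    raise CatalogError(
                        f"motif {motif_id} on reference {ref.id}: sequence "
                        f"{sub!r} violates consensus {consensus!r}")
        if self.code_reference:
            ref = self.references.get(self.code_reference)
            if ref is None:
                raise CatalogError(
                    f"code reference {self.code_reference!r} missing")
            for cid, pos in self.code_positions.items():
                if not (1 <= pos <= len(ref.sequence)):
                    raise CatalogError(f"code position {cid} outside reference")

    # -- serialization -----------------------------------------------------

    def serialize(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "motifs.tsv", "w") as fh:
            fh.write("domain_type\tsubtype_scope\tmotif_id\tstart\tend\t"
                     "consensus\tprevalent_length\toptional\n")
            for m in self.motifs:
                fh.write(f"{m.domain_type}\t{m.subtype_scope}\t{m.motif_id}\t"
                         f"{m.start}\t{m.end}\t{m.consensus}\t"
                         f"{m.prevalent_length}\t{int(m.optional)}\n")
        with open(directory / "references.fasta", "w") as fh:
            for ref in self.references.values():
                fh.write(f">{ref.id}|{ref.domain_type}|{ref.subtype}\n")
                for i in range(0, len(ref.sequence), 60):
                    fh.write(ref.sequence[i:i + 60] + "\n")
        with open(directory / "reference_spans.tsv", "w") as fh:
            fh.write("reference_id\tmotif_id\tstart\tend\n")
            for ref in self.references.values():
                for motif_id, start, end in ref.motif_spans:
                    fh.write(f"{ref.id}\t{motif_id}\t{start}\t{end}\n")
        with open(directory / "code_positions.json", "w") as fh:
            json.dump({"reference": self.code_reference,
                       "positions": self.code_positions,
                       "g_center_offset": self.g_center_offset,
                       "version": self.version}, fh, indent=1, sort_keys=True)


def _data_dir() -> Path:
    return Path(resources.files("nrpsarch") / "data")


def load_catalog(source: str | Path | None = None) -> MotifCatalog:
    """Load and validate a motif catalog.

    With ``source=None`` the built-in catalog bundled with the package is
    used; otherwise ``source`` must be a directory produced by
    :meth:`MotifCatalog.serialize`.
    """
    directory = Path(source) if source is not None else _data_dir()
    motifs: list[MotifDefinition] = []
    with open(directory / "motifs.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            motifs.append(MotifDefinition(
                domain_type=row["domain_type"],
                subtype_scope=row["subtype_scope"],
                motif_id=row["motif_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                consensus=row["consensus"],
                prevalent_length=int(row["prevalent_length"]),
                optional=bool(int(row["optional"])),
            ))
    spans: dict[str, list[tuple[str, int, int]]] = {}
    with open(directory / "reference_spans.tsv") as fh:
        fh.readline()
        for line in fh:
            rid, motif_id, start, end = line.rstrip("\n").split("\t")
            spans.setdefault(rid, []).append((motif_id, int(start), int(end)))
    references: dict[str, ReferenceDomain] = {}
    text = (directory / "references.fasta").read_text()
    records: list[tuple[str, str]] = []
    for chunk in text.split(">"):
        if not chunk.strip():
            continue
        lines = chunk.splitlines()
        records.append((lines[0].strip(), "".join(s.strip() for s in lines[1:])))
    for header_line, seq in records:
        rid, dtype, subtype = header_line.split("|")
        references[rid] = ReferenceDomain(
            id=rid, domain_type=dtype, subtype=subtype, sequence=seq.upper(),
            motif_spans=tuple(sorted(spans.get(rid, []), key=lambda s: s[1])))
    with open(directory / "code_positions.json") as fh:
        code = json.load(fh)
    catalog = MotifCatalog(
        motifs=motifs, references=references,
        code_reference=code.get("reference", ""),
        code_positions={k: int(v) for k, v in code.get("positions", {}).items()},
        g_center_offset=int(code.get("g_center_offset",
                                     _layouts.G_MOTIF_CENTER)),
        version=str(code.get("version", "1")))
    catalog.validate()
    return catalog


def build_builtin_catalog(seed: int = 20230515) -> MotifCatalog:
    """Construct the built-in catalog deterministically from the layouts.

    Used by ``scripts/build_reference_data.py`` to emit the vendored data
    files; the packaged files are the serialized output of this function.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    aas = _layouts.AMINO_ACIDS

    def realize(pattern: str) -> str:
        out = []
        for allowed in _layouts.parse_consensus(pattern):
            if allowed is None:
                out.append(aas[rng.integers(len(aas))])
            else:
                out.append(sorted(allowed)[0])
        return "".join(out)

    motifs: list[MotifDefinition] = []
    layout_spans: dict[str, dict[str, tuple[int, int]]] = {}
    for dtype, (entries, _pad) in _layouts.DOMAIN_LAYOUTS.items():
        pos = 0
        spans: dict[str, tuple[int, int]] = {}
        for motif_id, gap in entries:
            consensus = next(c for mid, c, _o in _layouts.MOTIF_TABLE[dtype]
                             if mid == motif_id)
            optional = next(o for mid, _c, o in _layouts.MOTIF_TABLE[dtype]
                            if mid == motif_id)
            length = consensus_length(consensus)
            start = pos + gap + 1
            end = start + length - 1
            spans[motif_id] = (start, end)
            motifs.append(MotifDefinition(
                domain_type=dtype, subtype_scope="all", motif_id=motif_id,
                start=start, end=end, consensus=consensus,
                prevalent_length=length, optional=optional))
            pos = end
        layout_spans[dtype] = spans
    for (dtype, subtype, motif_id), consensus in _layouts.MOTIF_OVERRIDES.items():
        start, end = layout_spans[dtype][motif_id]
        motifs.append(MotifDefinition(
            domain_type=dtype, subtype_scope=subtype, motif_id=motif_id,
            start=start, end=end, consensus=consensus,
            prevalent_length=end - start + 1, optional=False))

    def build_reference(rid: str, dtype: str, subtype: str) -> ReferenceDomain:
        entries, pad = _layouts.DOMAIN_LAYOUTS[dtype]
        seq = ""
        ref_spans: list[tuple[str, int, int]] = []
        for motif_id, gap in entries:
            seq += "".join(aas[rng.integers(len(aas))] for _ in range(gap))
            key = (dtype, subtype, motif_id)
            consensus = _layouts.MOTIF_OVERRIDES.get(
                key, next(c for mid, c, _o in _layouts.MOTIF_TABLE[dtype]
                          if mid == motif_id))
            start = len(seq) + 1
            seq += realize(consensus)
            ref_spans.append((motif_id, start, len(seq)))
        seq += "".join(aas[rng.integers(len(aas))] for _ in range(pad))
        return ReferenceDomain(id=rid, domain_type=dtype, subtype=subtype,
                               sequence=seq, motif_spans=tuple(ref_spans))

    references: dict[str, ReferenceDomain] = {}
    for dtype in DOMAIN_TYPES:
        rid = f"ref{dtype}"
        references[rid] = build_reference(rid, dtype, "canonical")
    # per-subtype C references share the canonical layout but carry
    # subtype-specific consensus overrides where defined
    for subtype in _layouts.SUBTYPE_IDS:
        rid = f"refC_{subtype}"
        references[rid] = build_reference(rid, "C", subtype)

    a_spans = dict(layout_spans["A"])
    code_positions: dict[str, int] = {}
    for cid, anchor, offset in _layouts.CODE_POSITION_SPEC:
        kind, motif_id = anchor.split(":")
        start, end = a_spans[motif_id]
        code_positions[cid] = (start + offset - 1 if kind == "in"
                               else end + offset)
    catalog = MotifCatalog(motifs=motifs, references=references,
                           code_reference="refA",
                           code_positions=code_positions)
    catalog.validate()
    return catalog
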