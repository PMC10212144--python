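"""Deterministic generators for every test surface.

All generators are pure functions of their spec and seed and emit ground
truth alongside the synthetic data, so locator, SCA and loop tests can
assert exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _layouts
from ._layouts import AMINO_ACIDS, DOMAIN_LAYOUTS, MODULE_LINKERS
from .catalog import MotifCatalog
from .stats import LabeledAlignment


@dataclass
class DomainRecipe:
    domain_type: str
    subtype: str = "canonical"
    gap_sd: float = 2.0
    mutation_rate: float = 0.0
    divergence: float = 0.3  # substitution rate vs the reference homolog
    include_optional: bool = True
    allow_fixed_mutations: bool = False
    # explicit gap overrides: motif_id -> gap length before that motif
    gap_overrides: dict[str, int] = field(default_factory=dict)
    pad_end_override: int | None = None
    # planted defects: motif_id -> number of residues dropped at its end
    shorten_motifs: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticDomain:
    sequence: str
    domain_type: str
    subtype: str
    motif_spans: dict[str, tuple[int, int]]  # ground truth, 1-based
    mutable: np.ndarray  # bool per position: True where mutation allowed


def _consensus_for(dtype: str, subtype: str, motif_id: str) -> str:
    key = (dtype, subtype, motif_id)
    if key in _layouts.MOTIF_OVERRIDES:
        return _layouts.MOTIF_OVERRIDES[key]
    return next(c for mid, c, _o in _layouts.MOTIF_TABLE[dtype]
                if mid == motif_id)


_CATALOG_CACHE: list = []


def _default_catalog() -> MotifCatalog:
    if not _CATALOG_CACHE:
        from .catalog import load_catalog

        _CATALOG_CACHE.append(load_catalog())
    return _CATALOG_CACHE[0]


def synth_domain(recipe: DomainRecipe, seed: int,
                 catalog: MotifCatalog | None = None) -> SyntheticDomain:
    """One synthetic domain homolog with recorded ground-truth spans.

    The domain is generated as a diverged copy of the catalog reference:
    intermotif segments are resized to lengths drawn around the layout
    means (insertions/deletions applied mid-segment) and every
    non-consensus position is substituted at ``divergence``; the fixed
    letters of motif consensus patterns are preserved unless
    ``allow_fixed_mutations`` is set.
    """
    if recipe.domain_type not in DOMAIN_LAYOUTS:
        raise ValueError(f"unknown domain type {recipe.domain_type!r}")
    catalog = catalog or _default_catalog()
    rng = np.random.default_rng(seed)
    ref_id = (f"refC_{recipe.subtype}"
              if recipe.domain_type == "C" and recipe.subtype != "canonical"
              else f"ref{recipe.domain_type}")
    ref = catalog.reference(ref_id)
    entries, pad_end = DOMAIN_LAYOUTS[recipe.domain_type]
    optional_ids = {mid for mid, _c, opt in
                    _layouts.MOTIF_TABLE[recipe.domain_type] if opt}
    ref_spans = {mid: (s, e) for mid, s, e in ref.motif_spans}

    def diverge(fragment: str, rate: float) -> str:
        chars = list(fragment)
        for i in np.nonzero(rng.random(len(chars)) < rate)[0]:
            choices = [a for a in AMINO_ACIDS if a != chars[i]]
            chars[i] = choices[rng.integers(19)]
        return "".join(chars)

    def resize(fragment: str, target: int) -> str:
        if target == len(fragment):
            return fragment
        if target < len(fragment):
            cut = len(fragment) - target
            mid = len(fragment) // 2
            return fragment[:mid - cut // 2] + fragment[mid + (cut + 1) // 2:]
        extra = "".join(AMINO_ACIDS[rng.integers(20)]
                        for _ in range(target - len(fragment)))
        mid = len(fragment) // 2
        return fragment[:mid] + extra + fragment[mid:]

    seq = ""
    mutable: list[bool] = []
    spans: dict[str, tuple[int, int]] = {}
    prev_end = 0  # reference coordinate of the previous motif end
    for motif_id, gap_mean in entries:
        rstart, rend = ref_spans[motif_id]
        ref_gap = ref.sequence[prev_end:rstart - 1]
        gap = recipe.gap_overrides.get(
            motif_id,
            max(0, int(round(rng.normal(gap_mean, recipe.gap_sd)))))
        if motif_id in optional_ids and not recipe.include_optional:
            prev_end = rend
            # fold the skipped motif into the surrounding intermotif: emit
            # the gap plus a random filler of the motif's length
            filler = resize(diverge(ref_gap, recipe.divergence),
                            gap + (rend - rstart + 1))
            seq += filler
            mutable.extend([True] * len(filler))
            continue
        fragment = resize(diverge(ref_gap, recipe.divergence), gap)
        seq += fragment
        mutable.extend([True] * len(fragment))
        consensus = _consensus_for(recipe.domain_type, recipe.subtype,
                                   motif_id)
        start = len(seq) + 1
        block = ref.sequence[rstart - 1:rend]
        for aa, allowed in zip(block, _layouts.parse_consensus(consensus)):
            if allowed is None:
                if rng.random() < recipe.divergence:
                    choices = [a for a in AMINO_ACIDS if a != aa]
                    aa = choices[rng.integers(19)]
                seq += aa
                mutable.append(True)
            else:
                choices = sorted(allowed)
                seq += choices[rng.integers(len(choices))]
                mutable.append(recipe.allow_fixed_mutations)
        drop = recipe.shorten_motifs.get(motif_id, 0)
        if drop:
            seq = seq[:len(seq) - drop]
            mutable = mutable[:len(seq)]
        spans[motif_id] = (start, len(seq))
        prev_end = rend
    if recipe.pad_end_override is not None:
        n_pad = recipe.pad_end_override
    else:
        n_pad = max(0, int(round(rng.normal(pad_end, recipe.gap_sd))))
    tail = resize(diverge(ref.sequence[prev_end:], recipe.divergence), n_pad)
    seq += tail
    mutable.extend([True] * len(tail))
    sequence = list(seq)
    mut = np.array(mutable)
    if recipe.mutation_rate > 0:
        hits = rng.random(len(sequence)) < recipe.mutation_rate
        for i in np.nonzero(hits & mut)[0]:
            old = sequence[i]
            choices = [a for a in AMINO_ACIDS if a != old]
            sequence[i] = choices[rng.integers(19)]
    return SyntheticDomain(sequence="".join(sequence),
                           domain_type=recipe.domain_type,
                           subtype=recipe.subtype, motif_spans=spans,
                           mutable=mut)


@dataclass
class SyntheticPathway:
    sequence: str
    domains: list[SyntheticDomain]
    offsets: list[int]  # 1-based start of each domain


def synth_pathway(recipes: list[DomainRecipe], seed: int,
                  linker_overrides: dict[int, int] | None = None
                  ) -> SyntheticPathway:
    """Concatenate synthetic domains with inter-domain linkers."""
    rng = np.random.default_rng(seed)
    domains = [synth_domain(r, int(rng.integers(2 ** 31)))
               for r in recipes]
    parts: list[str] = []
    offsets: list[int] = []
    pos = 0
    for i, dom in enumerate(domains):
        if i > 0:
            key = (domains[i - 1].domain_type, dom.domain_type)
            default = MODULE_LINKERS.get(key, 10)
            n_link = (linker_overrides or {}).get(i, default)
            parts.append("".join(AMINO_ACIDS[rng.integers(20)]
                                 for _ in range(n_link)))
            pos += n_link
        offsets.append(pos + 1)
        parts.append(dom.sequence)
        pos += len(dom.sequence)
    return SyntheticPathway(sequence="".join(parts), domains=domains,
                            offsets=offsets)


@dataclass
class AlignmentSpec:
    n_rows: int = 100
    n_cols: int = 40
    seed_consensus_prob: float = 0.7
    covarying_groups: list[list[int]] = field(default_factory=list)
    covariation_noise: float = 0.0
    label_name: str = "subtype"
    n_classes: int = 0
    class_probs: list[float] | None = None  # default: equiprobable
    label_coupled_columns: list[int] = field(default_factory=list)
    label_coupling: float = 1.0


def synth_labeled_alignment(spec: AlignmentSpec, seed: int
                            ) -> tuple[LabeledAlignment, dict]:
    """Alignment with planted covariation and label-coupled columns.

    Covarying groups share a per-row latent bit: rows with the bit set
    carry the group's alternative residue at every member column (flipped
    independently with ``covariation_noise``).  Label-coupled columns
    carry a class-specific residue with probability ``label_coupling``.
    """
    rng = np.random.default_rng(seed)
    n, m = spec.n_rows, spec.n_cols
    grouped = {j for grp in spec.covarying_groups for j in grp}
    coupled = set(spec.label_coupled_columns)
    if grouped & coupled:
        raise ValueError("covarying and label-coupled columns overlap")
    labels = None
    if spec.n_classes:
        probs = spec.class_probs or [1 / spec.n_classes] * spec.n_classes
        draws = rng.choice(spec.n_classes, size=n, p=probs)
        labels = [f"class{c}" for c in draws]
    cols = np.empty((n, m), dtype="<U1")
    consensus = [AMINO_ACIDS[rng.integers(20)] for _ in range(m)]
    for j in range(m):
        cons = consensus[j]
        others = [a for a in AMINO_ACIDS if a != cons]
        pick = rng.random(n) < spec.seed_consensus_prob
        for i in range(n):
            cols[i, j] = cons if pick[i] else others[rng.integers(19)]
    latents = {}
    for g, grp in enumerate(spec.covarying_groups):
        latent = rng.random(n) < 0.5
        latents[g] = latent
        for j in grp:
            a, b = consensus[j], _other(consensus[j])
            flip = rng.random(n) < spec.covariation_noise
            state = latent ^ flip
            cols[:, j] = np.where(state, b, a)
    if labels is not None:
        class_residues = {}
        for j in coupled:
            # give each class its own residue at this column
            perm = rng.permutation(20)
            class_residues[j] = {f"class{c}": AMINO_ACIDS[perm[c]]
                                 for c in range(spec.n_classes)}
            for i in range(n):
                if rng.random() < spec.label_coupling:
                    cols[i, j] = class_residues[j][labels[i]]
    rows = ["".join(cols[i]) for i in range(n)]
    ids = [f"seq{i}" for i in range(n)]
    aln = LabeledAlignment(
        ids=ids, rows=rows,
        labels={spec.label_name: labels} if labels is not None else {})
    truth = {"consensus": consensus,
             "covarying_groups": [list(g) for g in spec.covarying_groups],
             "latents": {g: v.tolist() for g, v in latents.items()},
             "label_coupled_columns": sorted(coupled)}
    return aln, truth


def _other(aa: str) -> str:
    i = AMINO_ACIDS.index(aa)
    return AMINO_ACIDS[(i + 7) % 20]


@dataclass
class LoopPopulationSpec:
    centers: list[tuple[int, int, int, int, int]]
    n_per_group: int = 40
    dispersion: float = 0.0  # SD of integer jitter per loop


def synth_loop_population(spec: LoopPopulationSpec, seed: int):
    """Loop vectors sampled around group centers, with ground truth."""
    from .loops import LoopVector

    rng = np.random.default_rng(seed)
    vectors: list[LoopVector] = []
    truth: list[int] = []
    for g, center in enumerate(spec.centers):
        for i in range(spec.n_per_group):
            jitter = (np.zeros(5) if spec.dispersion == 0 else
                      np.round(rng.normal(0, spec.dispersion, size=5)))
            lengths = tuple(int(max(0, c + d))
                            for c, d in zip(center, jitter))
            vectors.append(LoopVector(
                a_domain_id=f"g{g + 1}_{i}", lengths=lengths))
            truth.append(g + 1)
    return vectors, truth


def subtype_reference_msas(catalog: MotifCatalog, *, n_rows: int = 8,
                           substitution_rate: float = 0.08,
                           seed: int = 7_2023) -> dict[str, list[str]]:
    """Reference-style MSAs for every subtype model, from the catalog's
    per-subtype C references (plus the canonical E reference).

    Used once to emit the vendored subtype alignments; rows are ungapped
    perturbations of the subtype reference sequence, so each alignment is
    trivially consistent and subtype-distinctive.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    names = {s: f"refC_{s}" for s in _layouts.SUBTYPE_IDS}
    names["E"] = "refE"
    for name in list(names):
        base = catalog.reference(names[name]).sequence
        rows = []
        for _ in range(n_rows):
            chars = list(base)
            hits = np.nonzero(rng.random(len(chars))
                              < substitution_rate)[0]
            for i in hits:
                choices = [a for a in AMINO_ACIDS if a != chars[i]]
                chars[i] = choices[rng.integers(19)]
            rows.append("".join(chars))
        out[name] = rows
    return out
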