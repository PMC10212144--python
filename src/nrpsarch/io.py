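"""File-format readers and writers (FASTA, HMMER3 text, TSV tables)."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._layouts import AMINO_ACIDS
from .subtypes import ProfileHMM, SubtypeModelError


class FastaError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) preserving order.

    Duplicate ids are warned about and suffix-deduplicated (``id.2`` ...).
    """
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0] if title.split() else title
            if rid in seen:
                seen[rid] += 1
                warnings.warn(f"duplicate FASTA id {rid!r}; "
                              f"renamed to {rid}.{seen[rid]}")
                rid = f"{rid}.{seen[rid]}"
            else:
                seen[rid] = 1
            records.append((rid, seq.upper()))
    if not records:
        raise FastaError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Per-sequence label table: id column plus any of subtype/substrate/phylum."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in df.columns:
        raise ValueError(f"{path}: label table must have an 'id' column")
    return df.set_index("id")


def write_tsv(rows: list[dict], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- HMMER3 text profiles --------------------------------------------------

_HMMER_ALPH = "ACDEFGHIKLMNPQRSTVWY"


def read_hmm_profiles(path: str | Path) -> list[ProfileHMM]:
    """Parse HMMER3 ASCII profiles into scoreable models.

    Stored values are negative natural-log probabilities; ``*`` means
    probability zero.  The COMPO line (average match emissions) is used
    as the background when present, otherwise uniform.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("HMMER3"):
        raise SubtypeModelError(f"{path}: not a HMMER3 text file")
    models = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith("HMMER3"):
            i += 1
            continue
        name, leng = None, None
        while i < len(lines) and not lines[i].startswith("HMM "):
            if lines[i].startswith("NAME"):
                name = lines[i].split(maxsplit=1)[1].strip()
            elif lines[i].startswith("LENG"):
                leng = int(lines[i].split()[1])
            i += 1
        if i >= len(lines):
            raise SubtypeModelError(f"{path}: truncated profile {name!r}")
        alph = lines[i].split()[1:21]
        if "".join(alph) != _HMMER_ALPH:
            raise SubtypeModelError(
                f"{path}: unsupported alphabet for {name!r}")
        i += 2  # skip the HMM header pair
        background = np.full(20, 1.0 / 20)
        if lines[i].strip().startswith("COMPO"):
            background = _probs(lines[i].split()[1:21])
            i += 1
        i += 2  # node-0 insert emission + transition lines
        match_probs = np.zeros((leng, 20))
        transitions = {k: np.zeros(leng) for k in
                       ("mm", "mi", "md", "im", "ii", "dm", "dd")}
        for k in range(leng):
            fields = lines[i].split()
            if int(fields[0]) != k + 1:
                raise SubtypeModelError(
                    f"{path}: truncated profile {name!r} at node {k + 1}")
            match_probs[k] = _probs(fields[1:21])
            i += 2  # skip insert emissions
            tvals = _probs(lines[i].split()[:7])
            for key, v in zip(("mm", "mi", "md", "im", "ii", "dm", "dd"),
                              tvals):
                transitions[key][k] = v
            i += 1
        if not lines[i].strip().startswith("//"):
            raise SubtypeModelError(f"{path}: profile {name!r} not closed")
        i += 1
        models.append(ProfileHMM.from_probabilities(
            name or "profile", match_probs, transitions, background))
        if models[-1].length != leng:
            raise SubtypeModelError(f"{path}: LENG mismatch for {name!r}")
    return models


def _probs(fields: list[str]) -> np.ndarray:
    return np.array([0.0 if f == "*" else float(np.exp(-float(f)))
                     for f in fields])


def write_hmm_profile(model: ProfileHMM, path: str | Path) -> None:
    """Write a model in minimal HMMER3/f ASCII (round-trips through
    :func:`read_hmm_profiles`)."""
    probs = np.exp2(model.match_log_odds) * model.background[None, :]
    with open(path, "w") as fh:
        fh.write("HMMER3/f [nrpsarch]\n")
        fh.write(f"NAME  {model.name}\n")
        fh.write(f"LENG  {model.length}\n")
        fh.write("ALPH  amino\n")
        fh.write("HMM          " + "   ".join(_HMMER_ALPH) + "\n")
        fh.write("            m->m     m->i     m->d     i->m     i->i"
                 "     d->m     d->d\n")
        fh.write("  COMPO   " + _fmt(model.background) + "\n")
        fh.write("          " + _fmt(model.background) + "\n")
        fh.write("          " + _fmt(np.exp2([
            model.t["mm"][0], model.t["mi"][0], model.t["md"][0],
            model.t["im"][0], model.t["ii"][0], model.t["dm"][0],
            model.t["dd"][0]])) + "\n")
        for k in range(model.length):
            fh.write(f"{k + 1:7d} " + _fmt(probs[k]) + "\n")
            fh.write("          " + _fmt(model.background) + "\n")
            fh.write("          " + _fmt(np.exp2([
                model.t["mm"][k], model.t["mi"][k], model.t["md"][k],
                model.t["im"][k], model.t["ii"][k], model.t["dm"][k],
                model.t["dd"][k]])) + "\n")
        fh.write("//\n")


def _fmt(values) -> str:
    out = []
    for v in np.asarray(values, dtype=float):
        out.append("*" if v <= 0 else f"{-np.log(v):.5f}")
    return "  ".join(out)


assert _HMMER_ALPH == AMINO_ACIDS
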