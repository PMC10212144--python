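"""Regenerate the vendored catalog data files under src/nrpsarch/data/.

The bundled catalog (motif table, reference domains, code positions) and
the per-subtype reference alignments are deterministic functions of the
layout tables in nrpsarch._layouts and the seeds below.  Run from the
repository root:

    python scripts/build_reference_data.py
"""

from pathlib import Path

from nrpsarch.catalog import build_builtin_catalog
from nrpsarch.fixtures import subtype_reference_msas

DATA_DIR = Path(__file__).resolve().parent.parent / "src" / "nrpsarch" / "data"


def main() -> None:
    catalog = build_builtin_catalog()
    catalog.serialize(DATA_DIR)
    msa_dir = DATA_DIR / "subtype_msas"
    msa_dir.mkdir(parents=True, exist_ok=True)
    for name, rows in subtype_reference_msas(catalog).items():
        with open(msa_dir / f"{name}.fasta", "w") as fh:
            for i, row in enumerate(rows):
                fh.write(f">{name}_{i}\n")
                for j in range(0, len(row), 60):
                    fh.write(row[j:j + 60] + "\n")
    print(f"wrote catalog data to {DATA_DIR}")


if __name__ == "__main__":
    main()
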