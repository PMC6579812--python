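"""Shared fixtures: tiny reference genome, variants, and a synthetic PDB writer."""

import numpy as np
import pytest

from driverfuse.variant_windows import MutationPair, ReferenceSequenceStore, Variant


@pytest.fixture
def tiny_store() -> ReferenceSequenceStore:
    # chr1 1-based: a a a c g t a a a a a
    return ReferenceSequenceStore({"chr1": "aaacgtaaaaa", "chr2": "acgt" * 10})


@pytest.fixture
def tiny_variant() -> Variant:
    return Variant("chr1", 5, "G", "T", "driver")


def make_pair(ref_row: str, alt_center: str, label: str = "driver") -> MutationPair:
    """Build a MutationPair straight from a reference row string."""
    w = (len(ref_row) - 1) // 2
    alt_row = ref_row[:w] + alt_center + ref_row[w + 1 :]
    v = Variant("chrT", w + 1, ref_row[w].upper(), alt_center.upper(), label)
    return MutationPair(w=w, ref_row=ref_row, alt_row=alt_row, variant=v)


def random_pair(rng: np.random.Generator, w: int, alphabet: str = "acgt") -> MutationPair:
    row = "".join(rng.choice(list(alphabet), size=2 * w + 1))
    center = row[w] if row[w] in "acgt" else "a"
    # ensure the centre is a real base so ref != alt is satisfiable
    row = row[:w] + center + row[w + 1 :]
    alt = rng.choice([b for b in "acgt" if b != center])
    return make_pair(row, alt)


def write_synthetic_pdb(path, residues) -> None:
    """Write a minimal synthetic PDB: residues = [(chain, resnum, [(x,y,z), ...]), ...].

    Purely artificial coordinates for graph-construction tests; every atom is
    written as a carbon heavy atom.
    """
    lines = []
    serial = 1
    names = ["CA", "CB", "CG", "CD", "CE", "CZ"]
    for chain, resnum, coords in residues:
        for i, (x, y, z) in enumerate(coords):
            lines.append(
                f"ATOM  {serial:5d}  {names[i % len(names)]:<3s} GLY {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
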