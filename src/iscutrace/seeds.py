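"""Built-in synthetic seed alignments for the two protein families.

These are *synthetic* stand-ins for curated family seed alignments: random
reference sequences with the biologically meaningful positions pinned —
for the IscU-like scaffold, the three cluster-ligand cysteines (reference
positions 37, 63 and 106, the canonical ligand positions of the E. coli
scaffold), the chaperone-recognition motif LPPVK at positions 99-103, and
Ile at position 108; the CyaY-like seed is a plain single-domain family of
~100 residues with no pinned positions.

The seeds are generated from fixed internal seeds, independent of any user
seed, so every run of the package sees byte-identical profiles.  Cysteine
is excluded from the random portion of the reference so that exactly three
columns can reach full Cys conservation.
"""

from __future__ import annotations

import numpy as np

from .profiles import AMINO_ACIDS, SeedAlignment

ISCU_LENGTH = 128
ISCU_CYS_REFS = (37, 63, 106)
ISCU_MOTIF = "LPPVK"
ISCU_MOTIF_START = 99
ISCU_POS108 = 108
ISCU_POS108_STATE = "I"
CYAY_LENGTH = 106

_ISCU_SEED = 20140302
_CYAY_SEED = 20140303

#: positions (1-based) that never vary in the IscU seed rows
ISCU_CONSTRAINED_REFS = tuple(
    sorted(
        set(ISCU_CYS_REFS)
        | set(range(ISCU_MOTIF_START, ISCU_MOTIF_START + len(ISCU_MOTIF)))
        | {ISCU_POS108}
    )
)


def _random_reference(length: int, rng: np.random.Generator, exclude: str = "C") -> list[str]:
    alphabet = [a for a in AMINO_ACIDS if a not in exclude]
    return [alphabet[i] for i in rng.integers(len(alphabet), size=length)]


def _variant_rows(
    reference: list[str],
    constrained: set[int],
    n_rows: int,
    substitution_rate: float,
    rng: np.random.Generator,
    row_prefix: str,
    exclude: str = "C",
) -> list[tuple[str, str]]:
    alphabet = [a for a in AMINO_ACIDS if a not in exclude]
    rows = []
    for r in range(n_rows):
        chars = list(reference)
        for pos in range(len(chars)):
            if (pos + 1) in constrained:
                continue
            if rng.random() < substitution_rate:
                chars[pos] = alphabet[int(rng.integers(len(alphabet)))]
        rows.append((f"{row_prefix}{r + 1:02d}", "".join(chars)))
    return rows


def iscu_seed(n_rows: int = 12, substitution_rate: float = 0.15) -> SeedAlignment:
    """The IscU-family seed: gapless, with Cys/motif/108 columns invariant."""
    rng = np.random.default_rng(_ISCU_SEED)
    ref = _random_reference(ISCU_LENGTH, rng)
    for p in ISCU_CYS_REFS:
        ref[p - 1] = "C"
    for i, ch in enumerate(ISCU_MOTIF):
        ref[ISCU_MOTIF_START - 1 + i] = ch
    ref[ISCU_POS108 - 1] = ISCU_POS108_STATE
    rows = [("IscU_ref", "".join(ref))]
    rows += _variant_rows(
        ref, set(ISCU_CONSTRAINED_REFS), n_rows - 1, substitution_rate, rng, "IscU_seed"
    )
    return SeedAlignment(rows=rows, reference_row="IscU_ref")


def cyay_seed(n_rows: int = 12, substitution_rate: float = 0.15) -> SeedAlignment:
    """The CyaY/frataxin-like seed: a gapless single-domain family."""
    rng = np.random.default_rng(_CYAY_SEED)
    ref = _random_reference(CYAY_LENGTH, rng, exclude="")
    rows = [("CyaY_ref", "".join(ref))]
    rows += _variant_rows(ref, set(), n_rows - 1, substitution_rate, rng, "CyaY_seed", exclude="")
    return SeedAlignment(rows=rows, reference_row="CyaY_ref")
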