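"""Peptide sequence bookkeeping: the built-in leucine/serine peptide series,
mean hydrophobicity on the water/octanol scale, and helical-wheel geometry.

The built-in peptides are 21-residue designed amphipathic helices whose
hydrophobic leucine patch grows from 10 (L10) to 16 (L16) residues, with
serine filling the polar face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError

__all__ = [
    "PeptideSpec",
    "OCTANOL_SCALE",
    "BUILTIN_PEPTIDES",
    "mean_hydrophobicity",
    "helical_wheel",
    "hydrophobic_arc",
    "registry_fasta",
]

# Per-residue hydrophobicity (N-acetyl amino-acid amide water->octanol
# partitioning, free-energy based scale, dimensionless here).  Only the two
# residue types of the built-in series are tabulated; the derivation of the
# two constants from the registry means is documented in docs/methods.md.
OCTANOL_SCALE: dict[str, float] = {
    "L": 1.70,
    "S": -0.04,
}


def mean_hydrophobicity(sequence: str, scale: dict[str, float] | None = None) -> float:
    """Arithmetic mean of per-residue scale values, rounded to 3 decimals
    (round-half-even)."""
    if not sequence:
        raise InputError("empty sequence")
    scale = OCTANOL_SCALE if scale is None else scale
    total = 0.0
    for res in sequence:
        if res not in scale:
            raise InputError(f"residue {res!r} not present in the hydrophobicity scale")
        total += scale[res]
    return round(total / len(sequence), 3)


@dataclass(frozen=True)
class PeptideSpec:
    """A named peptide with its per-residue scale values and mean."""

    label: str
    sequence: str
    scale: tuple[float, ...] = field(default=(), compare=False)
    hydrophobicity: float = field(default=0.0, compare=False)

    @classmethod
    def from_sequence(cls, label: str, sequence: str) -> "PeptideSpec":
        vals = tuple(OCTANOL_SCALE[r] for r in sequence)
        return cls(label, sequence, vals, mean_hydrophobicity(sequence))

    def __len__(self) -> int:
        return len(self.sequence)


_BUILTIN_SEQUENCES = {
    "L10": "LSSLLSLLSSLLSSLSSLLSS",
    "L11": "LSSLLSLLSSLLSLLSSLLSS",
    "L12": "LSSLLSLLSSLLSLLSSLLSL",
    "L13": "LSLLLSLLSSLLSLLSSLLSL",
    "L14": "LSLLLSLLSLLLSLLSSLLSL",
    "L15": "LSLLLSLLSLLLSLLSLLLSL",
    "L16": "LSLLLLLLSLLLSLLSLLLSL",
}

BUILTIN_PEPTIDES: dict[str, PeptideSpec] = {
    label: PeptideSpec.from_sequence(label, seq) for label, seq in _BUILTIN_SEQUENCES.items()
}


def helical_wheel(sequence: str, rotation: float = 100.0) -> list[float]:
    """Per-residue azimuthal angles (deg) on an ideal helical wheel.

    residue i sits at (i * rotation) mod 360; the default 100 deg/residue is
    the ideal alpha-helix (period 18/5 turns)."""
    if not sequence:
        raise InputError("empty sequence")
    return [(i * rotation) % 360.0 for i in range(len(sequence))]


def hydrophobic_arc(sequence: str, hydrophobic: frozenset[str] = frozenset("L"),
                    rotation: float = 100.0) -> float:
    """Angular span (deg) of the largest contiguous arc of hydrophobic
    residues on the helical wheel.

    The wheel is scanned as a circular sequence of occupied angles; an
    all-hydrophobic sequence returns 360.
    """
    angles = helical_wheel(sequence, rotation)
    hydro = sorted({a for a, r in zip(angles, sequence) if r in hydrophobic})
    polar = sorted({a for a, r in zip(angles, sequence) if r not in hydrophobic}
                   - set(hydro))
    if not hydro:
        return 0.0
    if not polar:
        return 360.0
    # the hydrophobic arc is 360 minus the largest gap-free polar coverage;
    # equivalently: the widest angular window between polar residues that
    # contains hydrophobic ones.
    best = 0.0
    n = len(polar)
    for i in range(n):
        lo = polar[i]
        hi = polar[(i + 1) % n]
        span = (hi - lo) % 360.0
        inside = [a for a in hydro if 0.0 < (a - lo) % 360.0 < span]
        if inside:
            best = max(best, span)
    return best


def registry_fasta() -> str:
    """The built-in registry in FASTA form."""
    lines = []
    for spec in BUILTIN_PEPTIDES.values():
        lines.append(f">{spec.label} mean_hydrophobicity={spec.hydrophobicity:.3f}")
        lines.append(spec.sequence)
    return "\n".join(lines) + "\n"
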