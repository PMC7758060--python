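"""Synthetic two-lineage benchmark with a planted bridging theme.

The generator emulates the detection problem's structure: two deeply
diverged lineages of protein families whose members share one short
conserved element — a glycine-rich phosphate-binding loop with a
downstream aspartate anchor — embedded between flanks that carry no
cross-lineage signal.  Each family derives from its own random consensus;
planted families carry a mutated copy of the theme core (anchor
positions never mutated) between flanks mutated at a much higher rate,
so the theme is the only conserved element across lineages.

Everything is reproducible from the per-spec seeds, and a truth table
records which domains carry the theme and at which interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alphabet import AMINO_ACIDS
from .io_formats import DomainRecord, ThemeAlignment

# Default theme core: beta-strand hydrophobics, a Walker-A-like Gly-rich
# loop with the catalytic lysine, a helical stretch, and a downstream Asp.
DEFAULT_CORE = "VLIVGPSGSGKSTLLRAIAGNELDA"
DEFAULT_ANCHORS = (4, 7, 9, 10, 23)  # G, G, G, K, D


@dataclass(frozen=True)
class PlantedTheme:
    """The conserved element planted into both lineages."""

    core: str = DEFAULT_CORE
    anchor_positions: tuple[int, ...] = DEFAULT_ANCHORS

    def __post_init__(self):
        if len(self.core) < 20:
            raise ValueError("core must be >= 20 residues so planted hits "
                             "can pass the length filter")
        if any(not 0 <= a < len(self.core) for a in self.anchor_positions):
            raise ValueError("anchor positions must index into the core")


@dataclass(frozen=True)
class LineageSpec:
    """Shape and divergence parameters of one synthetic lineage."""

    lineage_label: str
    n_families: int = 6
    seqs_per_family: int = 4
    flank_length_range: tuple[int, int] = (60, 120)
    substitution_rate_theme: float = 0.4
    substitution_rate_flank: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.substitution_rate_theme <= 1.0:
            raise ValueError("theme substitution rate must be in [0,1]")
        if not 0.0 <= self.substitution_rate_flank <= 1.0:
            raise ValueError("flank substitution rate must be in [0,1]")
        if self.flank_length_range[0] < 1 or \
                self.flank_length_range[0] > self.flank_length_range[1]:
            raise ValueError("flank lengths must be positive and ordered")
        if self.n_families < 1 or self.seqs_per_family < 1:
            raise ValueError("family counts must be positive")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            frozen: frozenset[int] = frozenset()) -> str:
    """Substitute each non-frozen position with prob. rate (to a new residue)."""
    out = list(seq)
    for i in range(len(out)):
        if i in frozen:
            continue
        if rng.random() < rate:
            choices = [c for c in AMINO_ACIDS if c != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_lineages(spec_A: LineageSpec, spec_B: LineageSpec,
                      theme: PlantedTheme = PlantedTheme(),
                      fraction_planted: float = 0.5
                      ) -> tuple[list[DomainRecord], pd.DataFrame]:
    """Generate both lineages plus a truth table of planted intervals.

    In each lineage, round(fraction_planted * n_families) families carry
    the theme.  The truth table has columns domain_id, lineage, fgroup,
    planted, start, end (internal 0-based half-open interval).
    """
    if not 0.0 <= fraction_planted <= 1.0:
        raise ValueError("fraction_planted must be in [0,1]")
    records: list[DomainRecord] = []
    truth_rows = []
    anchors = frozenset(theme.anchor_positions)
    for spec in (spec_A, spec_B):
        rng = np.random.default_rng(spec.seed)
        n_planted = round(fraction_planted * spec.n_families)
        for fam in range(spec.n_families):
            planted = fam < n_planted
            lo, hi = spec.flank_length_range
            left_len = int(rng.integers(lo, hi + 1))
            right_len = int(rng.integers(lo, hi + 1))
            left_cons = _random_seq(rng, left_len)
            right_cons = _random_seq(rng, right_len)
            fgroup = f"{spec.lineage_label}.1.{fam + 1}"
            for s in range(spec.seqs_per_family):
                left = _mutate(rng, left_cons, spec.substitution_rate_flank)
                right = _mutate(rng, right_cons, spec.substitution_rate_flank)
                if planted:
                    core = _mutate(rng, theme.core,
                                   spec.substitution_rate_theme, anchors)
                    seq = left + core + right
                    start, end = left_len, left_len + len(core)
                else:
                    seq = left + right
                    start = end = -1
                did = f"{spec.lineage_label}_f{fam + 1}_s{s + 1}"
                records.append(DomainRecord(did, spec.lineage_label, fgroup, seq))
                if planted:
                    truth_rows.append({"domain_id": did,
                                       "lineage": spec.lineage_label,
                                       "fgroup": fgroup, "planted": True,
                                       "start": start, "end": end})
    truth = pd.DataFrame(truth_rows, columns=["domain_id", "lineage", "fgroup",
                                              "planted", "start", "end"])
    return records, truth


def generate_theme_msa(theme: PlantedTheme = PlantedTheme(), n_rows: int = 8,
                       rate: float = 0.2, seed: int = 0) -> ThemeAlignment:
    """Ungapped alignment of mutated core copies (anchors preserved)."""
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    anchors = frozenset(theme.anchor_positions)
    rows = tuple(_mutate(rng, theme.core, rate, anchors) for _ in range(n_rows))
    ids = tuple(f"theme_row_{i + 1}" for i in range(n_rows))
    return ThemeAlignment("planted_theme", rows, ids)


def generate_loop_coords(n_atoms: int = 11, noise_sigma: float = 0.0,
                         rotation: np.ndarray | None = None,
                         translation: np.ndarray | None = None,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A helix-like Cα trace and its rigidly moved, noise-perturbed copy.

    The base trace follows ideal alpha-helix geometry (rise 1.5 Å, turn
    100 degrees, radius 2.3 Å).  The copy is rotation @ x + translation
    plus i.i.d. Gaussian noise of noise_sigma per coordinate.
    """
    if n_atoms < 3:
        raise ValueError("need >= 3 atoms")
    rng = np.random.default_rng(seed)
    t = np.arange(n_atoms)
    ang = np.deg2rad(100.0) * t
    base = np.column_stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * t])
    if rotation is None:
        rotation = _random_rotation(rng)
    if translation is None:
        translation = rng.normal(scale=10.0, size=3)
    moved = base @ np.asarray(rotation).T + np.asarray(translation)
    if noise_sigma > 0:
        moved = moved + rng.normal(scale=noise_sigma, size=moved.shape)
    return base, moved


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
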