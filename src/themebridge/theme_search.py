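"""Profile scan of a domain database with empirical E-value calibration.

Each theme alignment is turned into a log-odds position-specific scoring
model; the model is locally aligned against every domain.  Significance
comes from a shuffle null: residues of randomly chosen database sequences
are permuted, the best local profile score on each shuffle is recorded,
and a Gumbel (extreme value) distribution is fitted to those scores.  The
E-value of a hit scoring s is then |db| * P_null(S >= s).

Hits are retained only if they clear all three filters: E-value below
``evalue_max`` (default 1e-3), profile coverage at least ``coverage_min``
(default 0.85, measured over theme columns), and alignment length at
least ``min_aln_length`` (default 20 residues).  A theme whose retained
hits span both lineages of interest is a candidate bridging theme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._alphabet import ALPHABET, ALPHABET_SIZE, encode
from . import _kernels
from .alignment import (GAP_EXTEND_DEFAULT, GAP_OPEN_DEFAULT,
                        profile_align_local)
from .gumbel import GumbelFit, fit_gumbel
from .io_formats import DomainRecord, ThemeAlignment

EVALUE_MAX_DEFAULT = 1e-3
COVERAGE_MIN_DEFAULT = 0.85
MIN_ALN_LENGTH_DEFAULT = 20


@dataclass(frozen=True)
class ThemeProfile:
    """Log-odds scoring model built from a theme alignment."""

    theme_id: str
    column_scores: np.ndarray  # (width, A)
    background: np.ndarray  # (A,) sums to 1

    def __post_init__(self):
        if self.column_scores.ndim != 2 or self.column_scores.shape[0] < 1:
            raise ValueError("profile must have width >= 1")
        if self.column_scores.shape[1] != ALPHABET_SIZE:
            raise ValueError("profile column count != alphabet size")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        if not np.isfinite(self.column_scores).any(axis=1).all():
            raise ValueError("every profile column needs a finite score")

    @property
    def width(self) -> int:
        return self.column_scores.shape[0]


def uniform_background() -> np.ndarray:
    """Uniform frequencies over the 20 amino acids ('X' gets none)."""
    bg = np.zeros(ALPHABET_SIZE)
    bg[:20] = 1.0 / 20.0
    return bg


def database_background(db: list[DomainRecord]) -> np.ndarray:
    """Residue frequencies of the database ('X' folded into the 20)."""
    counts = np.zeros(ALPHABET_SIZE)
    for d in db:
        codes = encode(d.sequence)
        counts += np.bincount(codes, minlength=ALPHABET_SIZE)
    counts = counts[:20]
    bg = np.zeros(ALPHABET_SIZE)
    if counts.sum() == 0:
        return uniform_background()
    bg[:20] = counts / counts.sum()
    return bg


def build_profile(t: ThemeAlignment, pseudocount: float = 1.0,
                  background: np.ndarray | None = None) -> ThemeProfile:
    """Column log-odds scores from a theme alignment.

    score(c, r) = log2((count(c,r) + pc*bg(r)) / ((n_c + pc) * bg(r)))
    with gap characters excluded from the counts; pc must be positive so
    unobserved residues get finite (negative) scores.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 to keep scores finite")
    bg = uniform_background() if background is None else np.asarray(background, float)
    w = t.width
    scores = np.zeros((w, ALPHABET_SIZE))
    # 'X' is never a profile target: give it the worst finite column score.
    safe_bg = np.where(bg > 0, bg, np.nan)
    for c in range(w):
        counts = np.zeros(ALPHABET_SIZE)
        for row in t.rows:
            ch = row[c]
            if ch != "-":
                counts[ALPHABET.index(ch)] += 1
        n_c = counts.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            col = np.log2((counts + pseudocount * safe_bg)
                          / ((n_c + pseudocount) * safe_bg))
        col[~np.isfinite(col)] = np.nanmin(col[np.isfinite(col)]) if np.isfinite(col).any() else 0.0
        scores[c] = col
    return ThemeProfile(t.theme_id, scores, bg)


@dataclass(frozen=True)
class ThemeHit:
    """One theme-to-domain local alignment with its filter statistics."""

    theme_id: str
    domain_id: str
    lineage: str
    fgroup: str
    interval: tuple[int, int]  # 0-based half-open on the domain
    score: float
    evalue: float
    coverage: float
    aln_length: int

    @property
    def passes_filters(self) -> bool:
        return passes_filters(self.evalue, self.coverage, self.aln_length)


def passes_filters(evalue: float, coverage: float, aln_length: int,
                   evalue_max: float = EVALUE_MAX_DEFAULT,
                   coverage_min: float = COVERAGE_MIN_DEFAULT,
                   min_aln_length: int = MIN_ALN_LENGTH_DEFAULT) -> bool:
    """The three retention filters, exactly as thresholds are stated."""
    return (evalue < evalue_max
            and coverage >= coverage_min
            and aln_length >= min_aln_length)


def calibrate_evalue(p: ThemeProfile, db: list[DomainRecord],
                     n_shuffles: int = 1000, seed: int = 0,
                     gap_open: float = GAP_OPEN_DEFAULT,
                     gap_extend: float = GAP_EXTEND_DEFAULT) -> GumbelFit:
    """Fit the Gumbel null of best local profile scores on shuffled sequences.

    Each draw permutes the residues of one randomly chosen database
    sequence and records the best local profile score on it.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    if not db:
        raise ValueError("empty database")
    rng = np.random.default_rng(seed)
    codes = [encode(d.sequence) for d in db]
    prof = np.ascontiguousarray(p.column_scores)
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        c = codes[rng.integers(len(codes))]
        shuffled = rng.permutation(c)
        scores[k] = _kernels.local_score(prof, shuffled, gap_open, gap_extend)
    if np.var(scores) == 0:
        raise ValueError(
            "degenerate (zero-variance) shuffle scores; increase n_shuffles "
            "or check the database")
    return fit_gumbel(scores)


def evalue(fit: GumbelFit, score: float, db_size: int) -> float:
    """E(s) = |db| * (1 - GumbelCDF(s))."""
    return db_size * fit.sf(score)


def scan_database(p: ThemeProfile, db: list[DomainRecord], fit: GumbelFit,
                  gap_open: float = GAP_OPEN_DEFAULT,
                  gap_extend: float = GAP_EXTEND_DEFAULT,
                  evalue_max: float = EVALUE_MAX_DEFAULT,
                  coverage_min: float = COVERAGE_MIN_DEFAULT,
                  min_aln_length: int = MIN_ALN_LENGTH_DEFAULT,
                  keep_all: bool = False) -> list[ThemeHit]:
    """Best local profile alignment per domain, filtered and sorted by E-value.

    Coverage is the fraction of profile columns consumed by the local
    alignment.  With ``keep_all`` the unfiltered hit list is returned
    (used for reporting the filter funnel).
    """
    hits: list[ThemeHit] = []
    for d in db:
        res = profile_align_local(p.column_scores, d.sequence,
                                  gap_open=gap_open, gap_extend=gap_extend)
        cov = res.a_length / p.width
        hit = ThemeHit(
            theme_id=p.theme_id, domain_id=d.id, lineage=d.lineage,
            fgroup=d.fgroup, interval=res.b_interval, score=res.score,
            evalue=evalue(fit, res.score, len(db)), coverage=cov,
            aln_length=len(res.aligned_pairs),
        )
        if keep_all or passes_filters(hit.evalue, hit.coverage, hit.aln_length,
                                      evalue_max, coverage_min, min_aln_length):
            hits.append(hit)
    hits.sort(key=lambda h: (h.evalue, h.domain_id))
    return hits


@dataclass(frozen=True)
class BridgingTheme:
    """A theme with retained hits in both lineages of interest."""

    theme_id: str
    hits_lineage_A: tuple[ThemeHit, ...]
    hits_lineage_B: tuple[ThemeHit, ...]

    def __post_init__(self):
        if not self.hits_lineage_A or not self.hits_lineage_B:
            raise ValueError("a bridging theme needs hits in both lineages")


def find_bridging_themes(hits: list[ThemeHit], lineage_A: str,
                         lineage_B: str,
                         known_lineages: set[str] | None = None) -> list[BridgingTheme]:
    """Themes whose retained hits include both lineages, ordered by theme_id.

    ``known_lineages`` (e.g. the labels present in the database) enables
    validation of the requested labels; a theme with hits in only one
    lineage is simply excluded, never an error.
    """
    if known_lineages is not None:
        for lab in (lineage_A, lineage_B):
            if lab not in known_lineages:
                raise ValueError(f"unknown lineage label {lab!r}; "
                                 f"known: {sorted(known_lineages)}")
    by_theme: dict[str, tuple[list[ThemeHit], list[ThemeHit]]] = {}
    for h in hits:
        slot = by_theme.setdefault(h.theme_id, ([], []))
        if h.lineage == lineage_A:
            slot[0].append(h)
        elif h.lineage == lineage_B:
            slot[1].append(h)
    out = []
    for tid in sorted(by_theme):
        a, b = by_theme[tid]
        if a and b:
            out.append(BridgingTheme(tid, tuple(a), tuple(b)))
    return out
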