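"""Statistical validation of cross-lineage theme matches.

For each pair of domains (one per lineage) matched to the same theme, the
domains are split into the theme-matching segment and the flanks.  The
matching segments are re-aligned — Smith–Waterman first, falling back to
Needleman–Wunsch when the local alignment covers less than half of either
segment — and the resulting score is compared with an extreme-value null
built from alignments of the first segment against random segments drawn
from the second segment's amino-acid composition (a multinomial model).
Pairs with p < 0.05 are retained, and per theme the k most convincing
pairs (most similar matching parts, most dissimilar flanks) are kept as
representatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._alphabet import ALPHABET, ALPHABET_SIZE, decode, encode
from . import _kernels
from .alignment import (GAP_EXTEND_DEFAULT, GAP_OPEN_DEFAULT, AlignmentResult,
                        SubstitutionMatrix, blosum62, needleman_wunsch,
                        smith_waterman)
from .gumbel import GumbelFit, fit_gumbel
from .io_formats import DomainRecord
from .theme_search import ThemeHit

P_MAX_DEFAULT = 0.05
N_RANDOM_DEFAULT = 1000
K_REPRESENTATIVES_DEFAULT = 2
SW_COVERAGE_FALLBACK = 0.5


@dataclass(frozen=True)
class AlignConfig:
    """Alignment parameters shared by the re-alignment steps."""

    matrix: Optional[SubstitutionMatrix] = None
    gap_open: float = GAP_OPEN_DEFAULT
    gap_extend: float = GAP_EXTEND_DEFAULT

    def mat(self) -> SubstitutionMatrix:
        return self.matrix or blosum62()


@dataclass(frozen=True)
class SegmentedDomain:
    """A domain split at its theme match: left flank + match + right flank."""

    domain_id: str
    left_flank: str
    match_segment: str
    right_flank: str

    @property
    def sequence(self) -> str:
        return self.left_flank + self.match_segment + self.right_flank


def segment_domain(d: DomainRecord, hit: ThemeHit) -> SegmentedDomain:
    """Split a domain at its theme-hit interval; empty flanks are allowed."""
    if hit.domain_id != d.id:
        raise ValueError(f"hit is for {hit.domain_id}, domain is {d.id}")
    s, e = hit.interval
    if not (0 <= s <= e <= len(d.sequence)):
        raise ValueError(f"hit interval [{s},{e}) outside domain of length "
                         f"{len(d.sequence)}")
    return SegmentedDomain(d.id, d.sequence[:s], d.sequence[s:e], d.sequence[e:])


def align_match_segments(a: str, b: str,
                         cfg: AlignConfig = AlignConfig()) -> tuple[AlignmentResult, str]:
    """Re-align two theme-matching segments; SW first, NW as fallback.

    If the local alignment covers less than half of either segment the
    global alignment is used instead and the returned mode is "NW".
    """
    if not a or not b:
        raise ValueError("match segments must be non-empty")
    sw = smith_waterman(a, b, cfg.mat(), cfg.gap_open, cfg.gap_extend)
    cov_a = sw.a_length / len(a)
    cov_b = sw.b_length / len(b)
    if cov_a < SW_COVERAGE_FALLBACK or cov_b < SW_COVERAGE_FALLBACK:
        return needleman_wunsch(a, b, cfg.mat(), cfg.gap_open, cfg.gap_extend), "NW"
    return sw, "SW"


def sample_random_segments(template: str, n: int, seed: int) -> list[str]:
    """n i.i.d. segments from the template's empirical residue composition.

    Each segment has the template's length; residues are drawn i.i.d.
    from the multinomial model estimated from the template.
    """
    if not template:
        raise ValueError("template must be non-empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    codes = encode(template)
    draws = rng.choice(codes, size=(n, len(codes)), replace=True)
    return [decode(row) for row in draws]


def _sample_code_matrix(template: str, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    codes = encode(template)
    return rng.choice(codes, size=(n, len(codes)), replace=True).astype(np.int8)


def pvalue_from_fit(fit: GumbelFit, s_obs: float) -> float:
    """Gumbel survival p = 1 - exp(-exp(-(s_obs - mu)/beta))."""
    return fit.sf(s_obs)


def empirical_pvalue(seg_a: str, seg_b: str, n: int = N_RANDOM_DEFAULT,
                     seed: int = 0, cfg: AlignConfig = AlignConfig(),
                     mode: str = "SW") -> tuple[GumbelFit, float]:
    """Extreme-value p-value of the seg_a/seg_b alignment score.

    Draws n random segments from seg_b's multinomial composition model,
    aligns each to seg_a with the same mode and penalties as the observed
    pair, fits a Gumbel to the null scores and evaluates the survival
    function at the observed score.

    Alignment scores are lattice-valued when the substitution matrix and
    gap penalties are integers; evaluating the continuous survival
    function exactly at a lattice point systematically miscalibrates the
    p-value, so a half-step continuity correction is applied whenever the
    null scores sit on the integer lattice.
    """
    if not seg_a or not seg_b:
        raise ValueError("segments must be non-empty")
    mat = cfg.mat()
    local = mode.upper() == "SW"
    if local:
        obs = smith_waterman(seg_a, seg_b, mat, cfg.gap_open, cfg.gap_extend)
    else:
        obs = needleman_wunsch(seg_a, seg_b, mat, cfg.gap_open, cfg.gap_extend)
    rng = np.random.default_rng(seed)
    segs = _sample_code_matrix(seg_b, n, rng)
    prof = np.ascontiguousarray(mat.scores[encode(seg_a).astype(np.intp), :])
    scores = _kernels.batch_scores(prof, segs, cfg.gap_open, cfg.gap_extend, local)
    if np.var(scores) == 0:
        raise ValueError("zero-variance null scores; segments too degenerate")
    fit = fit_gumbel(scores)
    s_eval = obs.score
    if np.allclose(scores, np.round(scores)) and float(obs.score).is_integer():
        s_eval -= 0.5  # continuity correction on the score lattice
    return fit, pvalue_from_fit(fit, s_eval)


def flank_similarity(sd_a: SegmentedDomain, sd_b: SegmentedDomain,
                     cfg: AlignConfig = AlignConfig()) -> float:
    """Sum of local alignment scores of left-vs-left and right-vs-right flanks."""
    total = 0.0
    for fa, fb in ((sd_a.left_flank, sd_b.left_flank),
                   (sd_a.right_flank, sd_b.right_flank)):
        if fa and fb:
            total += smith_waterman(fa, fb, cfg.mat(),
                                    cfg.gap_open, cfg.gap_extend).score
    return total


@dataclass(frozen=True)
class BridgeCandidate:
    """A cross-lineage domain pair matched to the same theme."""

    theme_id: str
    domain_A: str
    domain_B: str
    match_alignment: AlignmentResult
    match_mode: str  # "SW" | "NW"
    match_pvalue: float
    flank_similarity: float

    def __post_init__(self):
        if not 0.0 <= self.match_pvalue <= 1.0:
            raise ValueError("p-value outside [0,1]")

    @property
    def retained(self) -> bool:
        return self.match_pvalue < P_MAX_DEFAULT


def evaluate_pair(theme_id: str, dom_a: DomainRecord, hit_a: ThemeHit,
                  dom_b: DomainRecord, hit_b: ThemeHit,
                  n_random: int = N_RANDOM_DEFAULT, seed: int = 0,
                  cfg: AlignConfig = AlignConfig()) -> BridgeCandidate:
    """Full per-pair statistic: re-align, null-calibrate, score the flanks.

    The null is sampled from the lineage-B segment's composition and
    aligned to the lineage-A segment.
    """
    sd_a = segment_domain(dom_a, hit_a)
    sd_b = segment_domain(dom_b, hit_b)
    aln, aln_mode = align_match_segments(sd_a.match_segment, sd_b.match_segment, cfg)
    _, p = empirical_pvalue(sd_a.match_segment, sd_b.match_segment,
                            n=n_random, seed=seed, cfg=cfg, mode=aln_mode)
    fs = flank_similarity(sd_a, sd_b, cfg)
    return BridgeCandidate(theme_id, dom_a.id, dom_b.id, aln, aln_mode, p, fs)


def select_representatives(cands: list[BridgeCandidate],
                           k: int = K_REPRESENTATIVES_DEFAULT) -> list[BridgeCandidate]:
    """Per theme keep the k candidates with the most similar matching parts
    (smallest p-value) and most dissimilar flanks (smallest flank score);
    ties broken by (domain_B, domain_A) for determinism."""
    if k < 1:
        raise ValueError("k must be >= 1")
    by_theme: dict[str, list[BridgeCandidate]] = {}
    for c in cands:
        by_theme.setdefault(c.theme_id, []).append(c)
    out: list[BridgeCandidate] = []
    for tid in sorted(by_theme):
        ranked = sorted(by_theme[tid],
                        key=lambda c: (c.match_pvalue, c.flank_similarity,
                                       c.domain_B, c.domain_A))
        out.extend(ranked[:k])
    return out
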