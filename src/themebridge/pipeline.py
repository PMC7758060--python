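"""End-to-end orchestration: generate -> search -> bridge -> conserve -> overlay.

Every stage is deterministic given the config (every stochastic stage
derives its generator from the single config seed), so reruns with the
same config produce byte-identical reports.  Stage-by-stage pass/fail
counts are logged so the detection funnel (hits -> retained pairs ->
representatives) is auditable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import bridge, conservation, io_formats, overlay, synthetic, theme_search
from .bridge import AlignConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; seed is mandatory for any stochastic stage."""

    seed: int
    lineage_A: str = "2004"
    lineage_B: str = "2003"
    # search thresholds
    evalue_max: float = 1e-3
    coverage_min: float = 0.85
    min_aln_length: int = 20
    pseudocount: float = 1.0
    n_shuffles: int = 1000
    # bridge statistics
    p_max: float = 0.05
    n_random: int = 1000
    k_representatives: int = 2
    # alignment
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # conservation
    identity_threshold: float = 0.70
    # synthetic-data defaults
    n_families: int = 6
    seqs_per_family: int = 4
    fraction_planted: float = 0.5
    substitution_rate_theme: float = 0.4
    substitution_rate_flank: float = 0.95
    theme_msa_rows: int = 8
    theme_msa_rate: float = 0.2

    def __post_init__(self):
        if not (0 < self.coverage_min <= 1 and 0 < self.p_max < 1
                and 0 < self.identity_threshold <= 1):
            raise ValueError("threshold outside documented bounds")
        if self.evalue_max <= 0 or self.min_aln_length < 1:
            raise ValueError("threshold outside documented bounds")

    def config_hash(self) -> str:
        payload = ";".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def align_config(self) -> AlignConfig:
        return AlignConfig(gap_open=self.gap_open, gap_extend=self.gap_extend)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Flat ``key = value`` config file; CLI overrides win."""
        values: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: expected 'key = value', got {line!r}")
                k, v = (s.strip() for s in line.split("=", 1))
                values[k] = v
        values.update({k: v for k, v in overrides.items() if v is not None})
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        coerced = {}
        for k, v in values.items():
            if k not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, str):
                target = type(getattr(cls(seed=0), k))
                v = target(float(v)) if target in (int, float) else v
            coerced[k] = v
        if "seed" not in coerced:
            raise ValueError("config must set a seed")
        return cls(**coerced)


@dataclass
class BridgeRunResult:
    """Everything the bridge pipeline computed, plus its reports."""

    hits: list
    bridging_themes: list
    candidates: list
    representatives: list
    bridge_report: pd.DataFrame
    consensus_report: pd.DataFrame
    truth: pd.DataFrame | None = None


def _derive_seed(seed: int, salt: str) -> int:
    h = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def synthesize_inputs(config: RunConfig):
    """Build the two-lineage synthetic database and theme MSA from config."""
    theme = synthetic.PlantedTheme()
    spec_a = synthetic.LineageSpec(
        lineage_label=config.lineage_A, n_families=config.n_families,
        seqs_per_family=config.seqs_per_family,
        substitution_rate_theme=config.substitution_rate_theme,
        substitution_rate_flank=config.substitution_rate_flank,
        seed=_derive_seed(config.seed, "lineage_A"))
    spec_b = replace(spec_a, lineage_label=config.lineage_B,
                     seed=_derive_seed(config.seed, "lineage_B"))
    db, truth = synthetic.generate_lineages(spec_a, spec_b, theme,
                                            config.fraction_planted)
    msa = synthetic.generate_theme_msa(theme, n_rows=config.theme_msa_rows,
                                       rate=config.theme_msa_rate,
                                       seed=_derive_seed(config.seed, "theme_msa"))
    return db, truth, msa


def bridge_report_frame(candidates, p_max: float) -> pd.DataFrame:
    rows = [{
        "theme_id": c.theme_id,
        "domain_A": c.domain_A,
        "domain_B": c.domain_B,
        "mode": c.match_mode,
        "match_score": c.match_alignment.score,
        "match_pvalue": c.match_pvalue,
        "flank_similarity": c.flank_similarity,
        "retained": c.match_pvalue < p_max,
    } for c in candidates]
    return pd.DataFrame(rows, columns=["theme_id", "domain_A", "domain_B",
                                       "mode", "match_score", "match_pvalue",
                                       "flank_similarity", "retained"])


def run_bridge_pipeline(config: RunConfig, db=None, theme_msas=None,
                        truth=None, out_dir=None) -> BridgeRunResult:
    """Full chain: scan -> filter -> segment -> p-value -> representatives
    -> consensus.  With no explicit inputs the synthetic benchmark is used."""
    if db is None:
        db, truth, msa = synthesize_inputs(config)
        theme_msas = [msa]
    if not theme_msas:
        raise ValueError("no theme alignments supplied")
    logger.info("database: %d domains; %d theme(s); config %s",
                len(db), len(theme_msas), config.config_hash())

    background = theme_search.database_background(db)
    by_id = {d.id: d for d in db}
    acfg = config.align_config()

    all_hits: list[theme_search.ThemeHit] = []
    for msa in theme_msas:
        profile = theme_search.build_profile(msa, config.pseudocount, background)
        fit = theme_search.calibrate_evalue(
            profile, db, n_shuffles=config.n_shuffles,
            seed=_derive_seed(config.seed, f"calibrate:{msa.theme_id}"),
            gap_open=config.gap_open, gap_extend=config.gap_extend)
        hits = theme_search.scan_database(
            profile, db, fit, gap_open=config.gap_open,
            gap_extend=config.gap_extend, evalue_max=config.evalue_max,
            coverage_min=config.coverage_min,
            min_aln_length=config.min_aln_length)
        logger.info("theme %s: %d/%d domains pass E<%g, cov>=%g, len>=%d",
                    msa.theme_id, len(hits), len(db), config.evalue_max,
                    config.coverage_min, config.min_aln_length)
        all_hits.extend(hits)

    bridging = theme_search.find_bridging_themes(
        all_hits, config.lineage_A, config.lineage_B,
        known_lineages={d.lineage for d in db})
    logger.info("bridging themes: %d", len(bridging))

    candidates: list[bridge.BridgeCandidate] = []
    for bt in bridging:
        for ha in bt.hits_lineage_A:
            for hb in bt.hits_lineage_B:
                cand = bridge.evaluate_pair(
                    bt.theme_id, by_id[ha.domain_id], ha,
                    by_id[hb.domain_id], hb, n_random=config.n_random,
                    seed=_derive_seed(config.seed,
                                      f"pair:{bt.theme_id}:{ha.domain_id}:{hb.domain_id}"),
                    cfg=acfg)
                candidates.append(cand)
    retained = [c for c in candidates if c.match_pvalue < config.p_max]
    logger.info("cross-lineage pairs: %d evaluated, %d retained at p<%g",
                len(candidates), len(retained), config.p_max)
    reps = bridge.select_representatives(retained, config.k_representatives)
    logger.info("representatives kept: %d (k=%d)", len(reps),
                config.k_representatives)

    report = bridge_report_frame(candidates, config.p_max)

    # consensus/conservation over the theme region, after 70% redundancy
    # reduction of the theme alignment's rows (CD-HIT-style)
    msa = theme_msas[0]
    row_records = [io_formats.DomainRecord(
        msa.source_ids[i] if i < len(msa.source_ids) else f"row{i}",
        "theme", "theme", msa.rows[i].replace("-", "") or "X")
        for i in range(len(msa.rows))]
    clusters = conservation.cluster_sequences(
        row_records, config.identity_threshold,
        gap_open=config.gap_open, gap_extend=config.gap_extend)
    centroid_ids = {c.centroid_id for c in clusters}
    kept_rows = tuple(msa.rows[i] for i in range(len(msa.rows))
                      if (msa.source_ids[i] if i < len(msa.source_ids)
                          else f"row{i}") in centroid_ids)
    reduced = io_formats.ThemeAlignment(msa.theme_id, kept_rows)
    cons = conservation.consensus_profile(reduced)
    cons_report = conservation.conservation_table(cons)
    logger.info("conservation: %d/%d rows kept at %g%% identity",
                len(kept_rows), len(msa.rows), 100 * config.identity_threshold)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stamp = f"# themebridge {__version__} config {config.config_hash()}\n"
        io_formats.write_hits_table(all_hits, out_dir / "hits.tsv")
        for name, df in (("bridge_report.tsv", report),
                         ("consensus.tsv", cons_report)):
            with open(out_dir / name, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, sep="\t", index=False)

    return BridgeRunResult(all_hits, bridging, candidates, reps, report,
                           cons_report, truth)


def run_overlay(donor_path, acceptor_path, donor_sel, acceptor_sel,
                ligand_resname: str, out_path=None):
    """Superpose donor loop onto acceptor loop and transplant the ligand."""
    if not ligand_resname:
        raise ValueError("a ligand residue name is required")
    donor = io_formats.read_structure(donor_path)
    acceptor = io_formats.read_structure(acceptor_path)
    merged, sup = overlay.transplant_ligand(donor, acceptor, donor_sel,
                                            acceptor_sel, ligand_resname)
    logger.info("loop superposition: %d atoms, Calpha RMSD %.3f A",
                sup.n_atoms, sup.rmsd)
    if out_path is not None:
        remarks = [
            f"themebridge {__version__} ligand transplant",
            f"donor {donor_path} chain {donor_sel.chain} "
            f"{donor_sel.residue_range[0]}-{donor_sel.residue_range[1]}",
            f"acceptor {acceptor_path} chain {acceptor_sel.chain} "
            f"{acceptor_sel.residue_range[0]}-{acceptor_sel.residue_range[1]}",
            f"loop {donor_sel.atom_name} RMSD {sup.rmsd:.3f} A over {sup.n_atoms} atoms",
        ]
        io_formats.write_structure(merged, out_path, remarks)
    return merged, sup
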