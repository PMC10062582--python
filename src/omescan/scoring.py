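"""Sc_MapVal / Sc_FallOff scoring, ranking, and the end-to-end screen.

For each candidate ribose the hypothetical methyl carbon is probed in the map
(Sc_MapVal), and a second probe is placed by prolonging the O2'-methyl bond to
2.4 Å. Sc_FallOff is the ratio of the first to the second value: genuine methyl
density peaks at the predicted carbon and falls off along the bond direction
(ratio > 1), whereas flat density or an adjacent unmodelled feature (an ion,
say) does not. Candidates are ranked by Sc_MapVal descending; the falloff flag
uses a strict > threshold (default 1.5).

Division hazards: experimental maps contain near-zero and negative values
outside the molecular envelope, so the falloff is reported as undefined when
the denominator's magnitude is below a small fraction of the map RMS — such
records can never pass the falloff flag, and spurious infinite ratios never
reach a report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .density import DensityMap, interpolate
from .errors import OutsideMapError, SiteError
from .methylation import (AdductSpec, PlacedAdduct, choose_clash_free_torsion,
                          place_adduct, refine_torsion_against_map)
from .structure import AtomicModel, CandidateSite, select_candidates

__all__ = [
    "ScreenConfig", "ScoreRecord", "ScreenResult",
    "extended_position", "score_site", "rank_sites", "run_screen",
    "result_to_tsv", "result_to_json",
]

logger = logging.getLogger(__name__)

TSV_COLUMNS = ("chain", "seq_id", "torsion", "sc_mapval", "sc_falloff",
               "rank", "falloff_pass", "notes")


@dataclass(frozen=True)
class ScreenConfig:
    falloff_threshold: float = 1.5      # strict >, dimensionless
    denominator_epsilon: float = 0.05   # fraction of map RMS guarding the ratio
    refine: bool = True                 # density-guided torsion refinement
    torsion_step: float = 5.0           # degrees, clash/refinement scan step
    report_top_n: int = 15              # console summary size only

    def __post_init__(self):
        if self.falloff_threshold <= 0:
            raise ValueError("falloff_threshold must be > 0")
        if self.denominator_epsilon < 0:
            raise ValueError("denominator_epsilon must be >= 0")


@dataclass
class ScoreRecord:
    chain_id: str
    seq_id: int
    sc_mapval: float
    sc_falloff: Optional[float]        # None when the denominator is unreliable
    probe_position: np.ndarray         # methyl-carbon probe, Å
    extended_position: np.ndarray      # 2.4 Å bond-extension probe, Å
    torsion: float
    clash_free: bool
    refined: bool
    rank: int = 0                      # assigned by rank_sites
    falloff_pass: bool = False
    notes: tuple[str, ...] = ()

    @property
    def residue_ref(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_id)


@dataclass
class ScreenResult:
    records: list[ScoreRecord]
    excluded_sites: list[CandidateSite]
    config: ScreenConfig
    map_provenance: dict

    def record_for(self, chain_id: str, seq_id: int) -> Optional[ScoreRecord]:
        for r in self.records:
            if r.chain_id == chain_id and r.seq_id == seq_id:
                return r
        return None


def extended_position(placed: PlacedAdduct, spec: AdductSpec) -> np.ndarray:
    """The falloff probe: the O2'->methyl bond prolonged to ``probe_extension``.

    Collinear with the bond and at exactly ``probe_extension`` Å from the
    parent atom.
    """
    bond = np.asarray(placed.adduct_position) - np.asarray(placed.parent_position)
    norm = np.linalg.norm(bond)
    if norm == 0.0:
        raise SiteError("zero-length adduct bond vector")
    return np.asarray(placed.parent_position) + spec.probe_extension * bond / norm


def score_site(density: DensityMap, placed: PlacedAdduct, spec: AdductSpec,
               config: ScreenConfig) -> ScoreRecord:
    """Score one placed adduct. Both probes must lie inside the map."""
    ext = extended_position(placed, spec)
    probes = np.stack([placed.adduct_position, ext])
    values, inside = interpolate(density, probes)
    if not inside.all():
        raise OutsideMapError(
            f"residue {placed.site.chain_id}{placed.site.seq_id}: probe outside the map")
    v1, v2 = float(values[0]), float(values[1])
    notes: list[str] = []
    if not placed.clash_free:
        notes.append("clash")
    guard = config.denominator_epsilon * density.rms
    if abs(v2) > guard:
        falloff: Optional[float] = v1 / v2
    else:
        falloff = None
        notes.append("undefined-denominator")
    return ScoreRecord(
        chain_id=placed.site.chain_id, seq_id=placed.site.seq_id,
        sc_mapval=v1, sc_falloff=falloff,
        probe_position=np.array(placed.adduct_position), extended_position=ext,
        torsion=placed.torsion, clash_free=placed.clash_free,
        refined=placed.refined, notes=tuple(notes))


def rank_sites(records: list[ScoreRecord], config: ScreenConfig,
               excluded_sites: Optional[list[CandidateSite]] = None,
               map_provenance: Optional[dict] = None) -> ScreenResult:
    """Sort by Sc_MapVal descending (ties by chain then seq_id ascending),
    assign ranks 1..N, and apply the strict falloff threshold."""
    ordered = sorted(records, key=lambda r: (-r.sc_mapval, r.chain_id, r.seq_id))
    for i, rec in enumerate(ordered, start=1):
        rec.rank = i
        rec.falloff_pass = (rec.sc_falloff is not None
                            and rec.sc_falloff > config.falloff_threshold)
    return ScreenResult(records=ordered,
                        excluded_sites=list(excluded_sites or []),
                        config=config,
                        map_provenance=dict(map_provenance or {}))


def run_screen(model: AtomicModel, density: DensityMap, spec: AdductSpec,
               config: Optional[ScreenConfig] = None) -> ScreenResult:
    """The full screen: enumerate candidates, methylate each in silico with a
    clash-avoiding torsion, optionally settle the torsion into the density,
    probe the map at the methyl and bond-extended positions, and rank.

    The model and map must already share one coordinate frame; no fitting is
    performed. A failure at one site excludes that site with a reason instead
    of aborting the screen. Deterministic given inputs and config.
    """
    if config is None:
        config = ScreenConfig()
    candidates = select_candidates(model, spec)
    if not candidates:
        logger.warning("no candidate residues with codes %s in model",
                       sorted(spec.target_residue_codes))
    records: list[ScoreRecord] = []
    excluded: list[CandidateSite] = []
    for site in candidates:
        if not site.parent_atoms_present:
            logger.warning("excluding %s%s: %s", site.chain_id, site.seq_id,
                           site.reason_excluded)
            excluded.append(site)
            continue
        try:
            torsion, clash_free, _ = choose_clash_free_torsion(
                model, site, spec, step=config.torsion_step)
            placed = place_adduct(model, site, spec, torsion)
            if config.refine:
                placed = refine_torsion_against_map(model, placed, density, spec,
                                                    step=config.torsion_step)
            records.append(score_site(density, placed, spec, config))
        except SiteError as exc:
            logger.warning("excluding %s%s: %s", site.chain_id, site.seq_id, exc)
            excluded.append(CandidateSite(
                chain_id=site.chain_id, seq_id=site.seq_id,
                parent_atoms_present=site.parent_atoms_present,
                reason_excluded=str(exc)))
    provenance = {"map_stats": density.stats()}
    checksum = density.checksum()
    if checksum is not None:
        provenance["map_sha256"] = checksum
        provenance["map_path"] = density.source_path
    return rank_sites(records, config, excluded_sites=excluded,
                      map_provenance=provenance)


def _fmt_float(x: Optional[float]) -> str:
    return "NA" if x is None else format(x, ".6g")


def result_to_tsv(result: ScreenResult) -> str:
    """Fixed-column TSV, one row per scored candidate, rank order."""
    lines = ["\t".join(TSV_COLUMNS)]
    for r in result.records:
        lines.append("\t".join([
            r.chain_id, str(r.seq_id), format(r.torsion, ".2f"),
            _fmt_float(r.sc_mapval), _fmt_float(r.sc_falloff),
            str(r.rank), str(int(r.falloff_pass)),
            ";".join(r.notes) if r.notes else "-",
        ]))
    return "\n".join(lines) + "\n"


def result_to_json(result: ScreenResult) -> str:
    """Full result including provenance and exclusions, JSON-serialized."""
    payload = {
        "config": asdict(result.config),
        "map_provenance": result.map_provenance,
        "records": [{
            "chain": r.chain_id, "seq_id": r.seq_id, "rank": r.rank,
            "sc_mapval": r.sc_mapval, "sc_falloff": r.sc_falloff,
            "falloff_pass": r.falloff_pass, "torsion": r.torsion,
            "clash_free": r.clash_free, "refined": r.refined,
            "probe_position": [float(x) for x in r.probe_position],
            "extended_position": [float(x) for x in r.extended_position],
            "notes": list(r.notes),
        } for r in result.records],
        "excluded_sites": [{
            "chain": s.chain_id, "seq_id": s.seq_id,
            "reason": s.reason_excluded,
        } for s in result.excluded_sites],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
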