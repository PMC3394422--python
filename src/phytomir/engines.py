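"""The four predictor rule sets, re-implemented locally.

Each engine maps raw scan candidates to accepted TargetSites under the
decision rules the corresponding class of online plant predictors is
known for. They are deliberately named "*-like": they implement the
published decision rules, not byte-compatibility with any web service.

* WMD3-like: counts defects (mismatches + G:U wobbles + gaps, a G:U
  counted as one mismatch) with cutoff 5, plus energy ratio >= 70%;
  no region-specific weighting.
* UEA-like: forbids any central-region (9-11) defect, then applies a
  weighted-score cutoff and the 70% energy ratio.
* TAPIR-like: pure weighted score with core-region doubling (2-12)
  plus the 70% energy ratio.
* psRNATarget-like: weighted score only (no seed-specific attention,
  no ratio test) and classifies the functional type: a central-region
  mismatch marks translational repression, otherwise cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

from . import align as _align
from .datamodel import (
    GAP_STATES,
    PAIRED_STATES,
    FunctionalType,
    MatureMiRNA,
    PairState,
    PredictionSet,
    TargetSite,
    TranscriptRegion,
)
from .energy import DEFAULT_ENERGY_PARAMS, EnergyParams, energy_ratio

__all__ = [
    "WMD3LIKE",
    "UEALIKE",
    "TAPIRLIKE",
    "PSRNATARGETLIKE",
    "ENGINE_ORDER",
    "EngineConfig",
    "default_configs",
    "engine_wmd3like",
    "engine_uealike",
    "engine_tapirlike",
    "engine_psrnatargetlike",
    "run_all_engines",
]

WMD3LIKE = "WMD3LIKE"
UEALIKE = "UEALIKE"
TAPIRLIKE = "TAPIRLIKE"
PSRNATARGETLIKE = "PSRNATARGETLIKE"

ENGINE_ORDER: tuple[str, ...] = (WMD3LIKE, UEALIKE, TAPIRLIKE, PSRNATARGETLIKE)


@dataclass(frozen=True)
class EngineConfig:
    """Cutoffs and rule switches for one engine.

    ``mismatch_cutoff`` counts mismatches + G:U + gaps (WMD3-style);
    ``score_cutoff`` bounds the core-doubled weighted score. Cutoff
    comparisons are inclusive. Only the WMD3 mismatch cutoff (5) and
    the 70% ratio are classic published values; the score cutoffs are
    configurable toolkit defaults.
    """

    engine: str
    mismatch_cutoff: Optional[int] = None
    score_cutoff: Optional[float] = None
    energy_ratio_min: Optional[float] = 0.70
    central_must_pair: bool = False
    classify_functional: bool = False

    def __post_init__(self) -> None:
        if self.mismatch_cutoff is not None and self.mismatch_cutoff < 0:
            raise ValueError("mismatch_cutoff must be >= 0")
        if self.score_cutoff is not None and self.score_cutoff < 0:
            raise ValueError("score_cutoff must be >= 0")
        if self.energy_ratio_min is not None and not 0 <= self.energy_ratio_min <= 1:
            raise ValueError("energy_ratio_min must be in [0, 1]")


def default_configs() -> dict[str, EngineConfig]:
    return {
        WMD3LIKE: EngineConfig(engine=WMD3LIKE, mismatch_cutoff=5),
        UEALIKE: EngineConfig(engine=UEALIKE, score_cutoff=4.0, central_must_pair=True),
        TAPIRLIKE: EngineConfig(engine=TAPIRLIKE, score_cutoff=4.0),
        PSRNATARGETLIKE: EngineConfig(
            engine=PSRNATARGETLIKE,
            score_cutoff=3.0,
            energy_ratio_min=None,
            classify_functional=True,
        ),
    }


def _central_clean(site: TargetSite, params: _align.ScanParams) -> bool:
    duplex = site.duplex
    for state, pos in zip(duplex.pair_states, duplex.mirna_positions()):
        if params.central[0] <= pos <= params.central[1] and state not in PAIRED_STATES:
            return False
    return True


def _accepts(
    site: TargetSite, config: EngineConfig, params: _align.ScanParams
) -> bool:
    duplex = site.duplex
    if duplex is None:
        raise ValueError("engine rules need a duplex alignment on the site")
    if config.mismatch_cutoff is not None:
        defects = (
            duplex.count(PairState.MISMATCH)
            + duplex.count(PairState.GU_WOBBLE)
            + duplex.count(*GAP_STATES)
        )
        if defects > config.mismatch_cutoff:
            return False
    if config.score_cutoff is not None:
        if _align.weighted_score(duplex, params) > config.score_cutoff:
            return False
    if config.central_must_pair and not _central_clean(site, params):
        return False
    if config.energy_ratio_min is not None:
        if site.energy_ratio is None:
            raise ValueError("engine rules need energy_ratio annotated on the site")
        if site.energy_ratio < config.energy_ratio_min:
            return False
    return True


def classify_functional_type(
    site: TargetSite, params: _align.ScanParams = _align.DEFAULT_SCAN_PARAMS
) -> FunctionalType:
    """Cleavage unless a MISMATCH (not a G:U) falls in the central region."""
    duplex = site.duplex
    for state, pos in zip(duplex.pair_states, duplex.mirna_positions()):
        if (
            params.central[0] <= pos <= params.central[1]
            and state is PairState.MISMATCH
        ):
            return FunctionalType.TRANSLATION
    return FunctionalType.CLEAVAGE


def engine_wmd3like(
    site: TargetSite,
    config: Optional[EngineConfig] = None,
    params: _align.ScanParams = _align.DEFAULT_SCAN_PARAMS,
) -> bool:
    return _accepts(site, config or default_configs()[WMD3LIKE], params)


def engine_uealike(
    site: TargetSite,
    config: Optional[EngineConfig] = None,
    params: _align.ScanParams = _align.DEFAULT_SCAN_PARAMS,
) -> bool:
    return _accepts(site, config or default_configs()[UEALIKE], params)


def engine_tapirlike(
    site: TargetSite,
    config: Optional[EngineConfig] = None,
    params: _align.ScanParams = _align.DEFAULT_SCAN_PARAMS,
) -> bool:
    return _accepts(site, config or default_configs()[TAPIRLIKE], params)


def engine_psrnatargetlike(
    site: TargetSite,
    config: Optional[EngineConfig] = None,
    params: _align.ScanParams = _align.DEFAULT_SCAN_PARAMS,
) -> tuple[bool, FunctionalType]:
    cfg = config or default_configs()[PSRNATARGETLIKE]
    accepted = _accepts(site, cfg, params)
    ftype = classify_functional_type(site, params) if accepted else FunctionalType.UNSET
    return accepted, ftype


_ENGINE_PREDICATES = {
    WMD3LIKE: engine_wmd3like,
    UEALIKE: engine_uealike,
    TAPIRLIKE: engine_tapirlike,
}


def _scan_bound(
    configs: Mapping[str, EngineConfig], params: _align.ScanParams
) -> float:
    """Loosest weighted-score bound any engine-acceptable duplex can have."""
    bound = 0.0
    worst_unit = max(params.mismatch_weight, params.gu_weight) * params.core_multiplier
    gap_unit = params.gap_weight * params.core_multiplier
    for cfg in configs.values():
        if cfg.score_cutoff is not None:
            bound = max(bound, cfg.score_cutoff)
        if cfg.mismatch_cutoff is not None:
            gaps = min(params.max_indel, cfg.mismatch_cutoff)
            bound = max(
                bound, gaps * gap_unit + (cfg.mismatch_cutoff - gaps) * worst_unit
            )
    return bound


def run_all_engines(
    mirnas: Iterable[MatureMiRNA],
    transcripts: Iterable[TranscriptRegion],
    configs: Optional[Mapping[str, EngineConfig]] = None,
    scan_params: _align.ScanParams = _align.DEFAULT_SCAN_PARAMS,
    energy_params: EnergyParams = DEFAULT_ENERGY_PARAMS,
) -> PredictionSet:
    """Scan every miRNA against every transcript and pool engine verdicts.

    Each candidate window is aligned once, annotated with its energy
    ratio, then offered to all four engines; accepted copies are
    tagged with the accepting engine. Output order is deterministic:
    (transcript id, start, engine order, miRNA id).
    """
    cfgs = dict(default_configs())
    if configs:
        cfgs.update(configs)
    bound = _scan_bound(cfgs, scan_params)
    loose = replace(scan_params, max_penalty_score=bound)
    accepted: list[TargetSite] = []
    for transcript in transcripts:
        for mirna in mirnas:
            for cand in _align.scan_transcript(mirna, transcript, loose):
                site = replace(
                    cand, energy_ratio=energy_ratio(cand.duplex, mirna, energy_params)
                )
                for label in ENGINE_ORDER:
                    cfg = cfgs[label]
                    if label == PSRNATARGETLIKE or cfg.classify_functional:
                        ok, ftype = engine_psrnatargetlike(site, cfg, scan_params)
                        if ok:
                            accepted.append(
                                replace(site, engine=label, functional_type=ftype)
                            )
                    elif _accepts(site, cfg, scan_params):
                        accepted.append(replace(site, engine=label))
    order = {label: k for k, label in enumerate(ENGINE_ORDER)}
    accepted.sort(
        key=lambda s: (s.transcript_id, s.start, s.end, order.get(s.engine, 99), s.mirna_id)
    )
    return PredictionSet(tuple(accepted))
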