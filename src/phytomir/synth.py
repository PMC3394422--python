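"""Seeded generator of synthetic miRNAs, transcripts with planted target
sites, reference sets and degradome tables.

The generator plants the reverse complement of a miRNA (optionally
perturbed by a small edit list: mismatches, G:U wobbles, bulges) at a
known transcript coordinate, records the realized duplex as ground
truth, and derives which engines are expected to accept each site. A
fixed seed yields byte-identical output files, so every pipeline stage
is testable end-to-end with no downloads.

What it emulates: random-composition transcripts of realistic mRNA
length carrying isolated, coordinate-known complementary sites, plus
mRNA-level evidence tables whose true pairs score below the degradome
cutoff and whose decoys score above it. What it does not emulate:
codon structure, UTR base-composition bias, miRNA families with shared
seeds, or cleavage-position signal within degradome reads.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from . import align as _align
from .datamodel import (
    DegradomeRecord,
    DegradomeTable,
    DuplexAlignment,
    MatureMiRNA,
    PairState,
    ReferenceSet,
    Region,
    TargetSite,
    TranscriptRegion,
    WC_PARTNER,
)
from .energy import DEFAULT_ENERGY_PARAMS, EnergyParams, energy_ratio
from .engines import (
    ENGINE_ORDER,
    PSRNATARGETLIKE,
    EngineConfig,
    default_configs,
    engine_psrnatargetlike,
    _accepts,
)

__all__ = [
    "EditKind",
    "PlantSpec",
    "SynthConfig",
    "PlantedSite",
    "SynthDataset",
    "design_site",
    "plant_site",
    "generate_dataset",
]


class EditKind(enum.Enum):
    MISMATCH = "MISMATCH"
    GU = "GU"
    BULGE_TARGET = "BULGE_TARGET"  # extra target base (GAP_MIRNA state)
    BULGE_MIRNA = "BULGE_MIRNA"  # unopposed miRNA base (GAP_TARGET state)


@dataclass(frozen=True)
class PlantSpec:
    """Where and how to plant one site; edits are (miRNA position, kind)."""

    mirna_id: str
    transcript_id: str
    start: int
    region: Region = Region.UNSPLIT
    edits: tuple[tuple[int, EditKind], ...] = ()

    def __post_init__(self) -> None:
        positions = [pos for pos, _ in self.edits]
        if len(positions) != len(set(positions)):
            raise ValueError("edits must be at distinct miRNA positions")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 21 nt miRNAs, transcripts uniform over 300-2000 nt with
    uniform 25/25/25/25 base composition, one planted site per
    transcript, all planted pairs designated reference-true, true
    pairs degradome-supported (score below 4.5) with probability 0.9,
    decoys above the cutoff.
    """

    seed: int = 0
    n_mirnas: int = 8
    n_transcripts: int = 16
    mirna_length: int = 21
    transcript_length: tuple[int, int] = (300, 2000)
    gc_content: float = 0.5
    sites_per_transcript: int = 1
    region: Region = Region.UNSPLIT
    reference_fraction: float = 1.0
    degradome_support_prob: float = 0.9
    degradome_true_scores: tuple[float, float] = (1.0, 4.4)
    degradome_decoy_scores: tuple[float, float] = (4.6, 7.0)
    n_decoy_pairs: int = 10
    edit_menu: tuple[tuple[tuple[int, EditKind], ...], ...] = ((),)

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_transcripts, self.mirna_length) <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.sites_per_transcript < 0 or self.n_decoy_pairs < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.reference_fraction <= 1:
            raise ValueError("reference_fraction must be in [0, 1]")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")
        lo, hi = self.transcript_length
        need = self.sites_per_transcript * (self.mirna_length + 20)
        if lo > hi or lo < need:
            raise ValueError(
                f"transcript length range {self.transcript_length} cannot hold "
                f"{self.sites_per_transcript} site(s) of a {self.mirna_length} nt miRNA"
            )


_GU_TARGET = {"G": "U", "U": "G"}


def _mismatch_base(mirna_base: str) -> str:
    """First base (ACGU order) that is neither WC nor wobble partner."""
    for cand in "ACGU":
        if WC_PARTNER[mirna_base] != cand and _GU_TARGET.get(mirna_base) != cand:
            return cand
    raise AssertionError("unreachable")


def design_site(
    mirna: MatureMiRNA | str,
    edits: Iterable[tuple[int, EditKind]] = (),
) -> tuple[str, DuplexAlignment]:
    """Target-site sequence (5'->3') and ground-truth duplex for a miRNA.

    Starts from the perfect reverse complement and applies the edit
    list (miRNA positions, 1-based). GU edits require a G or U miRNA
    base; bulge edits insert or delete single target bases.
    """
    seq = mirna.seq if isinstance(mirna, MatureMiRNA) else mirna
    by_pos: dict[int, EditKind] = {}
    for pos, kind in edits:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"edit position {pos} outside miRNA 1..{len(seq)}")
        if pos in by_pos:
            raise ValueError("edits must be at distinct miRNA positions")
        by_pos[pos] = kind
    states: list[PairState] = []
    pairs: list[tuple[Optional[str], Optional[str]]] = []
    target_3to5: list[str] = []
    for pos in range(1, len(seq) + 1):
        m = seq[pos - 1]
        kind = by_pos.get(pos)
        if kind is EditKind.BULGE_TARGET:
            extra = _mismatch_base(m)
            states.append(PairState.GAP_MIRNA)
            pairs.append((None, extra))
            target_3to5.append(extra)
        if kind is EditKind.BULGE_MIRNA:
            states.append(PairState.GAP_TARGET)
            pairs.append((m, None))
            continue
        if kind is EditKind.MISMATCH:
            t = _mismatch_base(m)
            states.append(PairState.MISMATCH)
        elif kind is EditKind.GU:
            if m not in _GU_TARGET:
                raise ValueError(
                    f"GU edit at position {pos} needs a G or U miRNA base, got {m}"
                )
            t = _GU_TARGET[m]
            states.append(PairState.GU_WOBBLE)
        else:
            t = WC_PARTNER[m]
            states.append(PairState.WC_MATCH)
        pairs.append((m, t))
        target_3to5.append(t)
    duplex = DuplexAlignment(
        mirna_length=len(seq), pair_states=tuple(states), pairs=tuple(pairs)
    )
    return "".join(reversed(target_3to5)), duplex


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site."""

    spec: PlantSpec
    site: TargetSite
    expected_engines: frozenset[str]


def _expected_engines(
    site: TargetSite,
    configs: Mapping[str, EngineConfig],
    scan_params: _align.ScanParams,
) -> frozenset[str]:
    labels = set()
    for label in ENGINE_ORDER:
        cfg = configs[label]
        if label == PSRNATARGETLIKE or cfg.classify_functional:
            ok, _ = engine_psrnatargetlike(site, cfg, scan_params)
        else:
            ok = _accepts(site, cfg, scan_params)
        if ok:
            labels.add(label)
    return frozenset(labels)


def plant_site(
    transcript_seq: str,
    mirna: MatureMiRNA,
    spec: PlantSpec,
    scan_params: _align.ScanParams = _align.DEFAULT_SCAN_PARAMS,
    energy_params: EnergyParams = DEFAULT_ENERGY_PARAMS,
) -> tuple[str, TargetSite]:
    """Write the (edited) reverse complement of the miRNA into a transcript.

    Returns the new sequence and the realized ground-truth TargetSite
    (coordinates, duplex, weighted score, energy ratio).
    """
    site_seq, duplex = design_site(mirna, spec.edits)
    end = spec.start + len(site_seq)
    if not 0 <= spec.start < end <= len(transcript_seq):
        raise ValueError(
            f"planned interval [{spec.start}, {end}) outside transcript of "
            f"length {len(transcript_seq)}"
        )
    new_seq = transcript_seq[: spec.start] + site_seq + transcript_seq[end:]
    site = TargetSite(
        mirna_id=spec.mirna_id,
        transcript_id=spec.transcript_id,
        start=spec.start,
        end=end,
        duplex=duplex,
        region=spec.region,
        score=_align.weighted_score(duplex, scan_params),
        energy_ratio=energy_ratio(duplex, mirna, energy_params),
    )
    return new_seq, site


def _random_rna(rng: random.Random, length: int, gc: float) -> str:
    bases = []
    for _ in range(length):
        if rng.random() < gc:
            bases.append(rng.choice("GC"))
        else:
            bases.append(rng.choice("AU"))
    return "".join(bases)


@dataclass(frozen=True)
class SynthDataset:
    """One generated dataset plus its ground truth."""

    config: SynthConfig
    mirnas: tuple[MatureMiRNA, ...]
    transcripts: tuple[TranscriptRegion, ...]
    reference: ReferenceSet
    degradome: DegradomeTable
    truth: tuple[PlantedSite, ...]

    def true_pairs(self) -> set[tuple[str, str]]:
        return {p.site.pair for p in self.truth}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/TSV files; byte-identical for identical datasets."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirnas": outdir / "mirnas.fasta",
            "transcripts": outdir / "transcripts.fasta",
            "reference": outdir / "reference.tsv",
            "degradome": outdir / "degradome.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["mirnas"], "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m.id}\n{m.seq}\n")
        with open(paths["transcripts"], "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.transcript_id}\n")
                for k in range(0, len(t.seq), 70):
                    fh.write(t.seq[k : k + 70] + "\n")
        with open(paths["reference"], "w") as fh:
            fh.write("mirna_id\ttranscript_id\n")
            for m, t in sorted(self.reference.pairs):
                fh.write(f"{m}\t{t}\n")
        with open(paths["degradome"], "w") as fh:
            fh.write("mirna_id\ttranscript_id\tscore\n")
            for (m, t), score in sorted(self.degradome.scores.items()):
                fh.write(f"{m}\t{t}\t{score:.2f}\n")
        with open(paths["truth"], "w") as fh:
            fh.write(
                "mirna_id\ttranscript_id\tregion\tstart\tend\tscore\t"
                "edits\texpected_engines\n"
            )
            for planted in self.truth:
                site = planted.site
                edits = ",".join(
                    f"{pos}:{kind.value}" for pos, kind in planted.spec.edits
                ) or "-"
                engines = ",".join(sorted(planted.expected_engines)) or "-"
                fh.write(
                    f"{site.mirna_id}\t{site.transcript_id}\t{site.region.value}\t"
                    f"{site.start}\t{site.end}\t{site.score:.2f}\t{edits}\t{engines}\n"
                )
        return paths


def generate_dataset(
    config: SynthConfig,
    specs: Optional[Sequence[PlantSpec]] = None,
    configs: Optional[Mapping[str, EngineConfig]] = None,
    scan_params: _align.ScanParams = _align.DEFAULT_SCAN_PARAMS,
) -> SynthDataset:
    """Generate a complete synthetic input set, deterministic under seed.

    When ``specs`` is omitted, one spec per planted site is drawn:
    miRNAs are assigned round-robin across transcripts and the edit
    list cycles through ``config.edit_menu`` (default: perfect sites
    only). Explicit specs override placement entirely.
    """
    rng = random.Random(config.seed)
    engine_cfgs = dict(default_configs())
    if configs:
        engine_cfgs.update(configs)

    mirnas = tuple(
        MatureMiRNA(id=f"syn-miR{i + 1:03d}", seq=_random_rna(rng, config.mirna_length, config.gc_content))
        for i in range(config.n_mirnas)
    )
    raw_seqs = {
        f"SYNT{i + 1:04d}.1": _random_rna(
            rng, rng.randint(*config.transcript_length), config.gc_content
        )
        for i in range(config.n_transcripts)
    }

    if specs is None:
        specs = []
        tx_ids = sorted(raw_seqs)
        k = 0
        for tx_id in tx_ids:
            length = len(raw_seqs[tx_id])
            slots = _site_slots(
                rng, length, config.sites_per_transcript, config.mirna_length
            )
            for start in slots:
                mirna = mirnas[k % len(mirnas)]
                edits = config.edit_menu[k % len(config.edit_menu)]
                specs.append(
                    PlantSpec(
                        mirna_id=mirna.id,
                        transcript_id=tx_id,
                        start=start,
                        region=config.region,
                        edits=tuple(edits),
                    )
                )
                k += 1

    mirna_by_id = {m.id: m for m in mirnas}
    truth: list[PlantedSite] = []
    for spec in specs:
        if spec.transcript_id not in raw_seqs:
            raise ValueError(f"spec names unknown transcript {spec.transcript_id!r}")
        mirna = mirna_by_id.get(spec.mirna_id)
        if mirna is None:
            raise ValueError(f"spec names unknown miRNA {spec.mirna_id!r}")
        new_seq, site = plant_site(raw_seqs[spec.transcript_id], mirna, spec, scan_params)
        raw_seqs[spec.transcript_id] = new_seq
        truth.append(
            PlantedSite(
                spec=spec,
                site=site,
                expected_engines=_expected_engines(site, engine_cfgs, scan_params),
            )
        )

    transcripts = tuple(
        TranscriptRegion(transcript_id=tx_id, seq=seq, region=config.region)
        for tx_id, seq in sorted(raw_seqs.items())
    )

    planted_pairs = sorted({p.site.pair for p in truth})
    n_true = round(config.reference_fraction * len(planted_pairs))
    reference = ReferenceSet.from_pairs(planted_pairs[:n_true])

    records: list[DegradomeRecord] = []
    for pair in planted_pairs:
        if rng.random() < config.degradome_support_prob:
            score = rng.uniform(*config.degradome_true_scores)
        else:
            score = rng.uniform(*config.degradome_decoy_scores)
        records.append(DegradomeRecord(pair[0], pair[1], round(score, 2)))
    planted = set(planted_pairs)
    tx_ids = sorted(raw_seqs)
    attempts = 0
    while len(records) < len(planted_pairs) + config.n_decoy_pairs and attempts < 1000:
        attempts += 1
        pair = (rng.choice(mirnas).id, rng.choice(tx_ids))
        if pair in planted or any((r.mirna_id, r.transcript_id) == pair for r in records):
            continue
        records.append(
            DegradomeRecord(pair[0], pair[1], round(rng.uniform(*config.degradome_decoy_scores), 2))
        )

    return SynthDataset(
        config=config,
        mirnas=mirnas,
        transcripts=transcripts,
        reference=reference,
        degradome=DegradomeTable.from_records(records),
        truth=tuple(truth),
    )


def _site_slots(
    rng: random.Random, length: int, n_sites: int, site_len: int
) -> list[int]:
    """Non-overlapping planting starts, >= 10 nt apart and from the ends."""
    margin = 10
    slots: list[int] = []
    for _ in range(200):
        if len(slots) == n_sites:
            break
        start = rng.randint(margin, length - site_len - margin - 1)
        if all(abs(start - s) >= site_len + margin + 1 for s in slots):
            slots.append(start)
    if len(slots) < n_sites:
        raise ValueError(
            f"could not place {n_sites} sites of {site_len} nt on a {length} nt transcript"
        )
    return sorted(slots)
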