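"""Synthetic wet-up scenario generator with a known truth ledger.

Emits every table the pipeline consumes — genome catalogs, virome and
metagenome mapping records, SIP density-fraction profiles, DNA yields,
16S loss rates, and host/lysogeny evidence — from a single seeded
configuration, so each downstream stage can be tested against planted
ground truth without any external data.

Design notes:

* All randomness derives from one integer seed through named substreams,
  so outputs are bit-stable for a fixed config.
* Per-plot vOTU pools overlap partially; response archetypes drive the
  presence schedules, and the late-responder share is adjusted so the
  richness decline matches ``richness_decline_frac`` exactly at the
  schedule level.
* SIP profiles are Gaussian over a fixed density grid with a small linear
  tilt correction so each tube's DNA-weighted mean density equals the
  intended center exactly; at zero noise the APE chain then inverts to
  machine precision. Noise enters as jitter on recorded fraction
  densities (sd ``density_sd``) and on per-fraction genome masses.
* The viral DNA trajectory is deterministic given the config (noise lives
  in composition, not total biomass), so the configured fold change is
  reproduced exactly by the biomass summary.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import MAPPING_COLUMNS
from .lysogeny import ContigCoverage, LysogenAlignment, ProphageCoverage
from .hosts import SpacerHit, TaxonomyLineage
from .mortality import (
    DEFAULT_BURST_SIZES,
    DEFAULT_RRNA_COPIES_PER_CELL,
    MortalityInput,
)
from .qsip import DENSITY_INTERCEPT, DENSITY_SLOPE, density_shift_for_ape

DEFAULT_TIME_POINTS_H = (0, 3, 24, 48, 72, 168)
DEFAULT_RESPONSE_MIX = {
    "early": 0.35,
    "late": 0.15,
    "ubiquitous": 0.10,
    "zero_and_168": 0.10,
    "other": 0.30,
}

_LINEAGE_POOL = (
    "Bacteria;Actinobacteria;Actinomycetia;Streptomycetales;Streptomycetaceae;Streptomyces;Streptomyces_sp1",
    "Bacteria;Actinobacteria;Actinomycetia;Mycobacteriales;Mycobacteriaceae;Mycobacterium;Mycobacterium_sp1",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Rhizobiaceae;Rhizobium;Rhizobium_sp1",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas;Pseudomonas_sp1",
    "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus;Bacillus_sp1",
    "Bacteria;Acidobacteria;Acidobacteriia;Acidobacteriales;Acidobacteriaceae;Granulicella;Granulicella_sp1",
)

_TOOL_POOL = ("virsorter", "virsorter2", "vibrant", "deepvirfinder", "seeker")


class ConfigError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    n_plots: int = 3
    time_points_h: tuple = DEFAULT_TIME_POINTS_H
    n_votus: int = 300
    n_mags: int = 30
    richness_decline_frac: float = 0.5
    biomass_fold_change: float = 4.0
    frac_integrase: float = 0.17
    frac_circular: float = 0.15
    response_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_MIX)
    )
    true_ape: Mapping[str, float] | None = None
    frac_active: float = 0.5
    ape_choices: tuple = (0.1, 0.3, 0.6)
    n_sip_votus: int = 24
    n_sip_mags: int = 10
    abundance_cv: float = 0.3
    density_sd: float = 0.003
    profile_sd: float = 0.04
    sip_weight_cv: float = 0.01
    n_fractions: int = 5
    viral_read_fraction: float = 0.35
    dna_yield_base_ng_per_g: float = 2.0
    rrna_loss_rate: float = 6.0e8
    rrna_copies_per_cell: float = DEFAULT_RRNA_COPIES_PER_CELL
    burst_sizes: tuple = DEFAULT_BURST_SIZES
    frac_host_linked: float = 0.3
    n_lysogens: int = 3
    sample_total_reads: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        times = np.asarray(self.time_points_h, dtype=float)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ConfigError("time_points_h must be strictly increasing")
        mix_sum = sum(self.response_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigError(f"response_mix sums to {mix_sum}, expected 1")
        for name in (
            "richness_decline_frac",
            "frac_integrase",
            "frac_circular",
            "frac_active",
            "viral_read_fraction",
            "frac_host_linked",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if any(not 0.0 <= f <= 1.0 for f in self.response_mix.values()):
            raise ConfigError("response_mix fractions outside [0, 1]")
        if self.biomass_fold_change <= 0:
            raise ConfigError("biomass_fold_change must be positive")
        if self.true_ape is not None and any(
            not 0.0 <= a <= 1.0 for a in self.true_ape.values()
        ):
            raise ConfigError("true_ape values must lie in [0, 1]")
        if self.n_votus < 0 or self.n_mags < 0:
            raise ConfigError("genome counts must be non-negative")

    @property
    def metagenome_times_h(self) -> tuple:
        """Metagenome/SIP microcosms omit the 3 h time point."""
        return tuple(t for t in self.time_points_h if t != 3)

    @property
    def sip_times_h(self) -> tuple:
        """Isotope enrichment is only measurable after incubation."""
        return tuple(t for t in self.metagenome_times_h if t > 0)


@dataclass
class SyntheticDataset:
    config: ScenarioConfig
    votu_catalog: pd.DataFrame
    mag_catalog: pd.DataFrame
    virome_records: pd.DataFrame
    metagenome_records: pd.DataFrame
    dna_yields: pd.DataFrame
    viral_read_fraction: pd.DataFrame
    truth: dict
    fraction_records: pd.DataFrame | None = None
    fraction_abundance: pd.DataFrame | None = None
    sip_records: pd.DataFrame | None = None
    spacer_hits: list = field(default_factory=list)
    lysogen_alignments: list = field(default_factory=list)
    prophage_coverages: list = field(default_factory=list)
    contig_coverages: list = field(default_factory=list)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def resolve_response_mix(
    mix: Mapping[str, float], decline: float
) -> dict[str, float]:
    """Adjust the early/late split so the archetype schedules produce the
    requested richness decline.

    Richness at 0 h is driven by early + ubiquitous + zero_and_168, at
    168 h by ubiquitous + zero_and_168 + late. Holding the other three
    shares fixed and the early+late budget constant, the late share is
    solved from (u + z + late) = (1 - d)(early + u + z).
    """
    e, l = mix["early"], mix["late"]
    u, z = mix["ubiquitous"], mix["zero_and_168"]
    budget = e + l
    late = ((1.0 - decline) * budget - decline * (u + z)) / (2.0 - decline)
    late = min(max(late, 0.0), budget)
    out = dict(mix)
    out["late"] = late
    out["early"] = budget - late
    return out


def _archetype_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genomes over archetypes."""
    names = sorted(mix)
    raw = {k: mix[k] * n for k in names}
    counts = {k: int(np.floor(raw[k])) for k in names}
    short = n - sum(counts.values())
    for k in sorted(names, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _schedule(archetype: str, times: Sequence[float], rng) -> tuple:
    times = tuple(times)
    mid = [t for t in times if t not in (times[0], times[-1])]
    if archetype == "ubiquitous":
        return times
    if archetype == "early":
        return tuple(t for t in times if t <= 24)
    if archetype == "late":
        return tuple(t for t in times if t >= 48)
    if archetype == "zero_and_168":
        extra = mid[rng.integers(len(mid))] if mid else None
        return tuple(sorted({times[0], times[-1]} | ({extra} if extra else set())))
    # "other": interior-only block that matches no named rule
    return tuple(t for t in times if 0 < t <= 48)


def _breadth(rng, n, noisy: bool, lo: float = 0.81) -> np.ndarray:
    """Breadth for present genomes: Beta with mean 0.95, clipped so the
    detection cutoffs always pass; deterministic 0.95 at zero noise."""
    if not noisy:
        return np.full(n, 0.95)
    return np.clip(rng.beta(0.95 * 60, 0.05 * 60, size=n), lo, 1.0)


def generate_community(config: ScenarioConfig) -> SyntheticDataset:
    """Generate catalogs, virome/metagenome mapping records, DNA yields
    and the truth ledger for one wet-up scenario."""
    cat_rng = _rng(config.seed, "catalog")
    mem_rng = _rng(config.seed, "membership")
    ab_rng = _rng(config.seed, "abundance")
    br_rng = _rng(config.seed, "breadth")
    noisy = config.abundance_cv > 0

    plots = [f"plot{p + 1}" for p in range(config.n_plots)]
    times = config.time_points_h

    # --- vOTU catalog -------------------------------------------------
    n = config.n_votus
    votu_ids = [f"votu_{i:05d}" for i in range(n)]
    lengths = np.clip(
        cat_rng.lognormal(np.log(2.0e4), 0.5, size=n), 1.0e4, 2.0e5
    ).astype(int) if n else np.array([], dtype=int)
    circular = cat_rng.random(n) < config.frac_circular
    integrase = cat_rng.random(n) < config.frac_integrase
    tools = [
        ",".join(sorted(cat_rng.choice(_TOOL_POOL, size=2 + (i % 2), replace=False)))
        for i in range(n)
    ]
    votu_catalog = pd.DataFrame(
        {
            "id": votu_ids,
            "length_bp": lengths,
            "circular": circular.astype(int),
            "tools": tools,
            "integrase": integrase.astype(int),
            "source": ["virome"] * n,
            "host_lineage": [""] * n,
        }
    )

    # --- MAG catalog --------------------------------------------------
    m = config.n_mags
    mag_ids = [f"mag_{i:04d}" for i in range(m)]
    mag_catalog = pd.DataFrame(
        {
            "id": mag_ids,
            "length_bp": (
                np.clip(cat_rng.lognormal(np.log(4.0e6), 0.3, size=m), 1e6, 1.5e7)
            ).astype(int),
            "lineage": [_LINEAGE_POOL[i % len(_LINEAGE_POOL)] for i in range(m)],
        }
    )

    # --- archetypes and per-plot schedules ----------------------------
    mix = resolve_response_mix(config.response_mix, config.richness_decline_frac)
    counts = _archetype_counts(mix, n)
    archetypes = [k for k in sorted(counts) for _ in range(counts[k])]
    mem_rng.shuffle(archetypes)
    archetype = dict(zip(votu_ids, archetypes))

    membership: dict[str, tuple] = {}
    schedule: dict[tuple, tuple] = {}
    for gid in votu_ids:
        in_plot = mem_rng.random(config.n_plots) < 0.75
        if not in_plot.any():
            in_plot[mem_rng.integers(config.n_plots)] = True
        my_plots = tuple(p for p, ok in zip(plots, in_plot) if ok)
        membership[gid] = my_plots
        for p in my_plots:
            schedule[(gid, p)] = _schedule(archetype[gid], times, mem_rng)

    # --- virome mapping records ---------------------------------------
    base = {
        gid: {
            p: (
                ab_rng.lognormal(np.log(1e-3), 1.0) if noisy else 1e-3
            )
            for p in membership[gid]
        }
        for gid in votu_ids
    }
    grows = {"late", "ubiquitous"}
    votu_len = dict(zip(votu_ids, (int(x) for x in lengths)))
    rows = []
    for p in plots:
        for t in times:
            present = [
                gid
                for gid in votu_ids
                if p in membership[gid] and t in schedule[(gid, p)]
            ]
            if not present:
                continue
            mass = np.array(
                [
                    base[gid][p]
                    * (1.0 + 3.0 * t / times[-1] if archetype[gid] in grows else 1.0)
                    * (
                        ab_rng.lognormal(0.0, config.abundance_cv)
                        if noisy
                        else 1.0
                    )
                    for gid in present
                ]
            )
            total_mass = mass.sum()
            breadths = _breadth(br_rng, len(present), noisy)
            for k, gid in enumerate(present):
                rel = config.viral_read_fraction * mass[k] / total_mass
                glen = votu_len[gid]
                rows.append(
                    (
                        gid,
                        p,
                        t,
                        "virome",
                        "none",
                        -1,
                        int(round(rel * config.sample_total_reads)),
                        int(round(breadths[k] * glen)),
                        glen,
                        config.sample_total_reads,
                    )
                )
            # low-breadth decoys: a few absent genomes with spurious reads
            absent = [
                gid
                for gid in votu_ids
                if p in membership[gid] and t not in schedule[(gid, p)]
            ]
            for gid in absent[:: max(1, len(absent) // 3)][:3] if absent else []:
                glen = votu_len[gid]
                b = br_rng.uniform(0.05, 0.29) if noisy else 0.2
                rows.append(
                    (gid, p, t, "virome", "none", -1, 10,
                     int(round(b * glen)), glen, config.sample_total_reads)
                )
    virome_records = pd.DataFrame(rows, columns=MAPPING_COLUMNS)

    # --- MAG metagenome records ---------------------------------------
    mg_times = config.metagenome_times_h
    n_ubiq = int(round(0.45 * m))
    mag_ubiquitous = set(mag_ids[:n_ubiq])
    mag_present: dict[tuple, bool] = {}
    for gid in mag_ids:
        for p in plots:
            for t in mg_times:
                mag_present[(gid, p, t)] = (
                    gid in mag_ubiquitous or mem_rng.random() < 0.6
                )
    rows = []
    for p in plots:
        for t in mg_times:
            present = [gid for gid in mag_ids if mag_present[(gid, p, t)]]
            if not present:
                continue
            mass = np.array(
                [
                    ab_rng.lognormal(np.log(1e-2), config.abundance_cv)
                    if noisy
                    else 1e-2
                    for _ in present
                ]
            )
            breadths = _breadth(br_rng, len(present), noisy)
            for k, gid in enumerate(present):
                rel = 0.5 * mass[k] / mass.sum()
                glen = int(mag_catalog.loc[mag_catalog["id"] == gid, "length_bp"].iloc[0])
                rows.append(
                    (
                        gid, p, t, "metagenome", "none", -1,
                        int(round(rel * config.sample_total_reads)),
                        int(round(breadths[k] * glen)),
                        glen,
                        config.sample_total_reads,
                    )
                )
    metagenome_records = pd.DataFrame(rows, columns=MAPPING_COLUMNS)

    # --- DNA yields (deterministic trajectory) ------------------------
    t_last = times[-1]
    yield_rows = []
    vr_rows = []
    for p in plots:
        for t in times:
            viral_dna = (
                config.dna_yield_base_ng_per_g
                * config.viral_read_fraction
                * config.biomass_fold_change ** (t / t_last)
            )
            yield_rows.append(
                {
                    "plot": p,
                    "time_h": t,
                    "yield_ng_per_g": viral_dna / config.viral_read_fraction,
                }
            )
            vr_rows.append(
                {
                    "plot": p,
                    "time_h": t,
                    "viral_read_fraction": config.viral_read_fraction,
                }
            )

    # --- true APE assignment ------------------------------------------
    sip_votus = votu_ids[: min(config.n_sip_votus, n)]
    sip_mags = mag_ids[: min(config.n_sip_mags, m)]
    ape_rng = _rng(config.seed, "ape")
    true_ape = {}
    for gid in sip_votus + sip_mags:
        if config.true_ape is not None and gid in config.true_ape:
            true_ape[gid] = float(config.true_ape[gid])
        elif ape_rng.random() < config.frac_active:
            true_ape[gid] = float(ape_rng.choice(config.ape_choices))
        else:
            true_ape[gid] = 0.0

    truth = {
        "archetype": pd.Series(archetype, name="archetype"),
        "membership": membership,
        "schedule": schedule,
        "true_ape": true_ape,
        "sip_genomes": sip_votus + sip_mags,
        "hosts": {},
        "lysogens": [],
        "active_prophages": [],
        "mag_ubiquitous": sorted(mag_ubiquitous),
    }
    return SyntheticDataset(
        config=config,
        votu_catalog=votu_catalog,
        mag_catalog=mag_catalog,
        virome_records=virome_records,
        metagenome_records=metagenome_records,
        dna_yields=pd.DataFrame(yield_rows),
        viral_read_fraction=pd.DataFrame(vr_rows),
        truth=truth,
    )


def _tilted_profile(grid: np.ndarray, center: float, sd: float, amp: float) -> np.ndarray:
    """Gaussian profile over the grid, tilt-corrected so its discrete
    weighted mean equals ``center`` exactly."""
    w = amp * np.exp(-((grid - center) ** 2) / (2.0 * sd * sd))
    dev = grid - center
    denom = (w * dev * dev).sum()
    if denom > 0:
        lam = -(w * dev).sum() / denom
        w = np.maximum(w * (1.0 + lam * dev), 0.0)
        # a second pass removes any residual from the clipping
        denom = (w * dev * dev).sum()
        if denom > 0:
            lam = -(w * dev).sum() / denom
            w = np.maximum(w * (1.0 + lam * dev), 0.0)
    return w


def generate_sip_profiles(dataset: SyntheticDataset, config: ScenarioConfig | None = None) -> SyntheticDataset:
    """Fill in density-fraction records and per-fraction genome abundance
    encoding each genome's true APE; also emits SIP mapping records for
    the triplicate detection rule."""
    config = config or dataset.config
    rng = _rng(config.seed, "sip")
    noisy_d = config.density_sd > 0
    noisy_w = config.sip_weight_cv > 0

    plots = [f"plot{p + 1}" for p in range(config.n_plots)]
    grid = np.linspace(1.64, 1.80, config.n_fractions)
    genomes = dataset.truth["sip_genomes"]
    gc = {g: rng.uniform(0.35, 0.65) for g in genomes}
    w_light = {g: DENSITY_INTERCEPT + DENSITY_SLOPE * gc[g] for g in genomes}
    amp = {g: rng.lognormal(np.log(20.0), 0.5) if noisy_w else 20.0 for g in genomes}
    glen = {}
    for _, row in pd.concat([dataset.votu_catalog, dataset.mag_catalog]).iterrows():
        glen[row["id"]] = int(row["length_bp"])

    frac_rows, ab_rows, map_rows = [], [], []
    for p in plots:
        for t in config.sip_times_h:
            for treatment in ("16O", "18O"):
                measured = grid + (
                    rng.normal(0.0, config.density_sd, size=grid.size)
                    if noisy_d
                    else 0.0
                )
                masses = {}
                for g in genomes:
                    center = w_light[g]
                    if treatment == "18O" and dataset.truth["true_ape"][g] > 0:
                        center = density_shift_for_ape(
                            w_light[g], dataset.truth["true_ape"][g]
                        )
                    mg = _tilted_profile(grid, center, config.profile_sd, amp[g])
                    if noisy_w:
                        mg = mg * rng.lognormal(
                            0.0, config.sip_weight_cv, size=grid.size
                        )
                    masses[g] = mg
                background = 5000.0 * np.exp(
                    -((grid - 1.70) ** 2) / (2.0 * 0.02**2)
                ) + 50.0
                dna = background + sum(masses.values())
                for i in range(grid.size):
                    frac_rows.append(
                        {
                            "plot": p,
                            "treatment": treatment,
                            "time_h": t,
                            "fraction_index": i,
                            "density_gml": measured[i],
                            "dna_ng": dna[i],
                        }
                    )
                for g in genomes:
                    rel = masses[g] / dna
                    peak = int(np.argmax(masses[g]))
                    for i in range(grid.size):
                        ab_rows.append(
                            {
                                "genome_id": g,
                                "plot": p,
                                "treatment": treatment,
                                "time_h": t,
                                "fraction_index": i,
                                "rel_abund": rel[i],
                            }
                        )
                        breadth = 0.95 if i == peak else 0.30
                        map_rows.append(
                            (
                                g, p, t, "sip_fraction", treatment, i,
                                int(round(rel[i] * config.sample_total_reads)),
                                int(round(breadth * glen[g])),
                                glen[g],
                                config.sample_total_reads,
                            )
                        )

    dataset.fraction_records = pd.DataFrame(frac_rows)
    dataset.fraction_abundance = pd.DataFrame(ab_rows)
    dataset.sip_records = pd.DataFrame(map_rows, columns=MAPPING_COLUMNS)
    return dataset


def generate_mortality_inputs(
    dataset: SyntheticDataset, config: ScenarioConfig | None = None
) -> MortalityInput:
    """Plot-mean mortality-model inputs from the generated yields."""
    config = config or dataset.config
    merged = dataset.dna_yields.merge(
        dataset.viral_read_fraction, on=["plot", "time_h"]
    )
    merged["viral_dna"] = merged["yield_ng_per_g"] * merged["viral_read_fraction"]
    per_time = merged.groupby("time_h")["viral_dna"].mean().sort_index()
    mean_len = (
        float(dataset.votu_catalog["length_bp"].mean())
        if len(dataset.votu_catalog)
        else 2.1254e4
    )
    return MortalityInput(
        time_h=tuple(per_time.index),
        viral_dna_ng_per_g=tuple(per_time.to_numpy()),
        rrna_loss_rate=tuple(config.rrna_loss_rate for _ in per_time),
        mean_genome_len_bp=mean_len,
        rrna_copies_per_cell=config.rrna_copies_per_cell,
        burst_sizes=tuple(config.burst_sizes),
    )


def generate_evidence_tables(
    dataset: SyntheticDataset, config: ScenarioConfig | None = None
) -> SyntheticDataset:
    """Plant host links, decoy spacer hits, lysogen alignments and
    prophage coverage records; records all planted truth in the ledger."""
    config = config or dataset.config
    rng = _rng(config.seed, "evidence")
    votu_ids = list(dataset.votu_catalog["id"])

    n_linked = int(round(config.frac_host_linked * len(votu_ids)))
    linked = votu_ids[:n_linked]
    spacer_hits: list[SpacerHit] = []
    hosts: dict[str, str] = {}
    for k, gid in enumerate(linked):
        lineage = _LINEAGE_POOL[int(rng.integers(len(_LINEAGE_POOL)))]
        full = TaxonomyLineage.from_string(lineage)
        if rng.random() < 0.3:
            # two sources that agree only down to a random rank
            depth = int(rng.integers(2, 6))
            alt = TaxonomyLineage(full.ranks[:depth] + ("Alt_" + full.ranks[depth],))
            preds = [full, alt]
            hosts[gid] = TaxonomyLineage(full.ranks[:depth]).to_string()
        else:
            preds = [full]
            hosts[gid] = full.to_string()
        for j, lin in enumerate(preds):
            slen = int(rng.integers(28, 41))
            spacer_hits.append(
                SpacerHit(
                    spacer_id=f"spacer_{k:04d}_{j}",
                    source=("mag", "unbinned_contig", "spacer_db")[j % 3],
                    source_lineage=lin,
                    votu_id=gid,
                    mismatches=int(rng.integers(0, 2)),
                    gaps=0,
                    align_len=slen,
                    spacer_len=slen,
                    evalue=1e-12,
                )
            )
    # decoys violating exactly one filter each
    decoy_pool = votu_ids[n_linked : n_linked + 3]
    for i, gid in enumerate(decoy_pool):
        slen = 32
        kwargs = dict(
            spacer_id=f"decoy_{i}",
            source="mag",
            source_lineage=TaxonomyLineage.from_string(_LINEAGE_POOL[0]),
            votu_id=gid,
            mismatches=0,
            gaps=0,
            align_len=slen,
            spacer_len=slen,
            evalue=1e-12,
        )
        if i % 3 == 0:
            kwargs["mismatches"] = 2
        elif i % 3 == 1:
            kwargs["gaps"] = 1
        else:
            kwargs["align_len"] = slen - 1
        spacer_hits.append(SpacerHit(**kwargs))

    # lysogen alignments: planted candidates pass every threshold
    lysogens = votu_ids[: config.n_lysogens]
    alignments: list[LysogenAlignment] = []
    for i, gid in enumerate(lysogens):
        alignments.append(
            LysogenAlignment(
                votu_id=gid,
                contig_id=f"contig_{i:03d}",
                pct_identity=float(rng.uniform(92.0, 99.5)),
                align_len=int(rng.integers(10_000, 30_000)),
                evalue=1e-150,
                flank_len=int(rng.integers(10_001, 40_000)),
            )
        )
    fail_cases = [
        {"pct_identity": 85.0},
        {"evalue": 1e-50},
        {"flank_len": 8_000},
        {"align_len": 5_000},
    ]
    for i, override in enumerate(fail_cases):
        kwargs = dict(
            votu_id=f"decoy_lys_{i}",
            contig_id=f"contig_d{i:02d}",
            pct_identity=95.0,
            align_len=12_000,
            evalue=1e-150,
            flank_len=15_000,
        )
        kwargs.update(override)
        alignments.append(LysogenAlignment(**kwargs))

    # contig coverage: candidates vs sub-threshold decoys
    contig_covs = [
        ContigCoverage(f"contig_{i:03d}", 60_000, int(rng.integers(5_000, 40_000)))
        for i in range(config.n_lysogens)
    ] + [
        ContigCoverage("contig_low", 60_000, 900),
        ContigCoverage("contig_full", 60_000, 60_000),
    ]

    # prophage coverage: half active, half dormant
    mag_ids = list(dataset.mag_catalog["id"])
    prophages = []
    active = []
    for i, gid in enumerate(mag_ids[: min(6, len(mag_ids))]):
        is_active = i % 2 == 0
        flank = float(rng.uniform(4.0, 8.0))
        ratio = rng.uniform(2.0, 4.0) if is_active else rng.uniform(0.8, 1.2)
        prophages.append(
            ProphageCoverage(
                mag_id=gid,
                contig_id=f"{gid}_c1",
                start=10_000,
                end=50_000,
                prophage_cov=flank * ratio,
                flank_cov=flank,
            )
        )
        if is_active:
            active.append(gid)

    dataset.spacer_hits = spacer_hits
    dataset.lysogen_alignments = alignments
    dataset.contig_coverages = contig_covs
    dataset.prophage_coverages = prophages
    dataset.truth["hosts"] = hosts
    dataset.truth["lysogens"] = list(lysogens)
    dataset.truth["active_prophages"] = active
    return dataset


def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Full scenario: community, SIP profiles and evidence tables."""
    ds = generate_community(config)
    generate_sip_profiles(ds, config)
    generate_evidence_tables(ds, config)
    return ds
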