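"""Synthetic cfDNA cohort generator.

The generator emulates what a targeted, non-destructive methylation-seq assay
of plasma cfDNA sees, at the level the pipeline consumes: nucleosome-protected
fragments, per-CpG methylation counts, and an unmethylated lambda spike-in.

Fragment model
    Nucleosome centres sit on a lattice (default 185 bp spacing — core +
    linker) phased to the region anchor. Each molecule picks a lattice
    centre, jitters it by Normal(0, jitter_sd) (positional fuzziness), draws
    a length from Normal(167, sd) truncated to [50, 250] bp (the
    mono-nucleosome mode), and is placed midpoint-at-centre. Around TSS/PAS
    anchors, lattice sites within the nucleosome-depleted region (NDR) have
    their sampling weight scaled down by ``ndr_depth``, and per-site molecule
    counts are Poisson, so depletion lowers both local and region-level
    coverage.

Class effects
    A configurable subset of regions per modality is *informative*: there the
    cancer class uses a different parameter (methylation rate, NDR depth,
    jitter SD, or fragment-length mean with depth compensation — the last
    perturbs the protection score while leaving mean coverage unchanged).
    Per-sample latent shifts (global methylation tone, NDR tone, chromatin
    disorder, sequencing depth) are shared across regions within a sample,
    which is what keeps single-modality classifiers imperfect and their
    errors partly independent across modalities.

Everything is reproducible from (config, seed), and the ground-truth record
lists exactly the regions where class parameters differ.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import derive_seed
from .errors import UsageError
from .io import FragmentSet, TargetRegion, write_fragments, write_regions
from .methylation import write_calls

LAMBDA_CONTIG = "lambda"


@dataclass(frozen=True)
class ModalityEffect:
    """A planted class difference: ``n_regions`` regions get ``value`` in cancer."""

    n_regions: int
    value: float


@dataclass
class SimConfig:
    """Generator parameters; defaults are the standard study conditions."""

    n_cancer: int = 30
    n_control: int = 30
    # panel geometry
    n_cpg_regions: int = 40
    n_tss: int = 20
    n_pas: int = 20
    cpg_region_len: int = 150
    nuc_flank: int = 1000               # TSS/PAS regions span anchor ± 1 kb
    n_cpg_per_region: int = 2
    # fragment model
    frag_len_mean: float = 167.0
    frag_len_sd: float = 12.0
    nucleosome_spacing: int = 185
    ndr_halfwidth: int = 300
    ndr_depth: float = 0.3              # NDR site weight (both classes, baseline)
    jitter_sd: float = 4.0              # positional SD (bp), baseline
    depth: float = 300.0                # expected fragments per nucleosome region
    # methylation model
    meth_rate: float = 0.25             # per-CpG methylation probability, baseline
    meth_coverage: float = 60.0
    # spike-in
    lambda_conversion: float = 0.995
    lambda_sites: int = 100
    lambda_coverage: float = 100.0
    # per-sample latent variability
    depth_cv: float = 0.10
    meth_sample_sd: float = 0.04
    ndr_sample_sd: float = 0.10
    jitter_sample_sd: float = 1.2
    # planted class effects per modality (cancer value in informative regions)
    effects: dict[str, ModalityEffect] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for rate in (self.meth_rate, self.ndr_depth, self.lambda_conversion):
            if not 0.0 <= rate <= 1.0:
                raise UsageError(f"rate {rate} outside [0, 1]")
        if self.jitter_sd < 0:
            raise UsageError("jitter_sd must be >= 0")
        if min(self.n_cancer, self.n_control) < 1:
            raise UsageError("need >= 1 sample per class")
        if 2 * self.ndr_halfwidth >= 2 * self.nuc_flank:
            raise UsageError("NDR wider than the nucleosome region")


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study conditions.

    ``null``
        identical class parameters — the no-signal calibration condition.
    ``strong_occupancy``
        a strong NDR-fill effect (per-feature effect size around d = 2) in
        20% of nucleosome regions; other modalities carry no signal.
    ``complementary``
        disjoint informative regions per modality with moderate effects, so
        every single modality is imperfect and stacking has room to help.
    ``concordant``
        all four modalities carry strong effects (in their own regions).
    """
    effects: dict[str, ModalityEffect]
    if name == "null":
        effects = {}
    elif name == "strong_occupancy":
        effects = {"occupancy": ModalityEffect(8, 0.80)}
    elif name == "complementary":
        effects = {
            "methylation": ModalityEffect(8, 0.33),
            "occupancy": ModalityEffect(7, 0.46),
            "fuzziness": ModalityEffect(7, 4.8),
            "wps": ModalityEffect(6, 158.0),
        }
    elif name == "concordant":
        effects = {
            "methylation": ModalityEffect(8, 0.40),
            "occupancy": ModalityEffect(8, 0.80),
            "fuzziness": ModalityEffect(8, 9.0),
            "wps": ModalityEffect(8, 150.0),
        }
    else:
        raise UsageError(f"unknown preset {name!r}")
    return SimConfig(effects=effects, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

def build_panel(config: SimConfig) -> tuple[list[TargetRegion], list[TargetRegion]]:
    """(methylation panel, nucleosome panel) on the simulator mini-genome."""
    meth = []
    for i in range(config.n_cpg_regions):
        s = 500 + i * 400
        meth.append(TargetRegion("chr2", s, s + config.cpg_region_len,
                                 f"CPG_{i:03d}", "cpg_marker"))
    nuc = []
    pitch = 2 * config.nuc_flank + 1000
    for i in range(config.n_tss):
        s = 1000 + i * pitch
        nuc.append(TargetRegion("chr1", s, s + 2 * config.nuc_flank,
                                f"TSS_{i:03d}", "tss", s + config.nuc_flank))
    off = 1000 + config.n_tss * pitch
    for i in range(config.n_pas):
        s = off + i * pitch
        nuc.append(TargetRegion("chr1", s, s + 2 * config.nuc_flank,
                                f"PAS_{i:03d}", "pas", s + config.nuc_flank))
    return meth, nuc


def cpg_positions(region: TargetRegion, n: int) -> np.ndarray:
    """Evenly spaced CpG coordinates inside a marker region."""
    return region.start + ((np.arange(n) + 1) * region.length // (n + 1))


def generate_genome(config: SimConfig, seed: int) -> dict[str, str]:
    """Random mini-genome covering the panel (for the dinucleotide diagnostic)."""
    rng = np.random.default_rng(derive_seed(seed, 91))
    pitch = 2 * config.nuc_flank + 1000
    sizes = {
        "chr1": 2000 + (config.n_tss + config.n_pas) * pitch,
        "chr2": 1000 + config.n_cpg_regions * 400,
    }
    return {c: "".join(rng.choice(list("ACGT"), size=n))
            for c, n in sizes.items()}


# ---------------------------------------------------------------------------
# per-region generators
# ---------------------------------------------------------------------------

def _truncated_lengths(rng: np.random.Generator, n: int, mean: float,
                       sd: float, lo: int = 50, hi: int = 250) -> np.ndarray:
    lengths = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    for _ in range(20):
        bad = (lengths < lo) | (lengths > hi)
        if not bad.any():
            break
        lengths[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(np.int64)
    return np.clip(lengths, lo, hi)


def simulate_region_fragments(region: TargetRegion, rng: np.random.Generator,
                              depth: float, jitter_sd: float,
                              ndr_depth: float, config: SimConfig,
                              frag_len_mean: float | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Fragment (starts, ends) for one region of one sample.

    When ``frag_len_mean`` overrides the global mean, the per-site rate is
    scaled by the inverse length ratio so expected coverage mass stays put.
    """
    spacing = config.nucleosome_spacing
    anchor = region.anchor if region.anchor is not None else (
        (region.start + region.end) // 2)
    k_lo = int(np.floor((region.start - anchor) / spacing))
    k_hi = int(np.ceil((region.end - anchor) / spacing))
    centers = anchor + spacing * np.arange(k_lo, k_hi + 1)
    weights = np.ones(len(centers))
    if region.region_type in ("tss", "pas"):
        weights[np.abs(centers - anchor) <= config.ndr_halfwidth] = ndr_depth
    flm = config.frag_len_mean if frag_len_mean is None else frag_len_mean
    rate = depth / len(centers) * (config.frag_len_mean / flm)
    counts = rng.poisson(rate * weights)
    mids = np.repeat(centers, counts).astype(np.float64)
    if jitter_sd > 0:
        mids += rng.normal(0.0, jitter_sd, size=len(mids))
    mids = np.rint(mids).astype(np.int64)
    lengths = _truncated_lengths(rng, len(mids), flm, config.frag_len_sd)
    starts = mids - (lengths - 1) // 2
    return starts, starts + lengths


def simulate_methylation(positions: np.ndarray, chrom: str, rate: float,
                         coverage: float, rng: np.random.Generator,
                         ) -> pd.DataFrame:
    """Binomial per-CpG calls: coverage ~ Poisson, methylated ~ Binomial."""
    total = rng.poisson(coverage, size=len(positions))
    meth = rng.binomial(total, np.clip(rate, 0.0, 1.0))
    return pd.DataFrame({"chrom": chrom, "pos": positions.astype(np.int64),
                         "n_meth": meth, "n_total": total})


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """In-memory cohort: inputs for every pipeline stage plus ground truth."""

    config: SimConfig
    meth_panel: list[TargetRegion]
    nuc_panel: list[TargetRegion]
    sample_sheet: pd.DataFrame
    fragments: dict[str, FragmentSet]
    methylation: dict[str, pd.DataFrame]
    lambda_calls: dict[str, pd.DataFrame]
    ground_truth: dict

    def write(self, outdir) -> None:
        """Write the standard pipeline input files plus ground_truth.json."""
        os.makedirs(outdir, exist_ok=True)
        write_regions(self.meth_panel, os.path.join(outdir, "meth_panel.bed"))
        write_regions(self.nuc_panel, os.path.join(outdir, "nuc_panel.bed"))
        sheet = self.sample_sheet.copy()
        sheet["fragments"] = [f"{s}.frag.bedpe" for s in sheet["sample_id"]]
        sheet["methylation"] = [f"{s}.meth.tsv" for s in sheet["sample_id"]]
        sheet["lambda"] = [f"{s}.lambda.tsv" for s in sheet["sample_id"]]
        sheet.to_csv(os.path.join(outdir, "sample_sheet.tsv"), sep="\t",
                     index=False)
        for sid in sheet["sample_id"]:
            write_fragments(self.fragments[sid],
                            os.path.join(outdir, f"{sid}.frag.bedpe"), "bedpe")
            write_calls(self.methylation[sid],
                        os.path.join(outdir, f"{sid}.meth.tsv"))
            write_calls(self.lambda_calls[sid],
                        os.path.join(outdir, f"{sid}.lambda.tsv"))
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)
        genome = generate_genome(self.config, self.config.seed)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for contig, seq in genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full cohort under ``config`` (reproducible from its seed)."""
    seed = config.seed
    rng = np.random.default_rng(derive_seed(seed, 1))
    meth_panel, nuc_panel = build_panel(config)

    # pick informative regions per modality; nucleosome-panel modalities draw
    # without replacement from a shared shuffle so their sets are disjoint
    informative: dict[str, list[str]] = {m: [] for m in
                                         ("methylation", "occupancy",
                                          "fuzziness", "wps")}
    eff = config.effects
    if "methylation" in eff:
        n = min(eff["methylation"].n_regions, len(meth_panel))
        idx = rng.choice(len(meth_panel), size=n, replace=False)
        informative["methylation"] = sorted(meth_panel[i].name for i in idx)
    nuc_order = rng.permutation(len(nuc_panel))
    cursor = 0
    n_nuc_effects = sum(1 for m in ("occupancy", "fuzziness", "wps") if m in eff)
    for mod in ("occupancy", "fuzziness", "wps"):
        if mod in eff:
            # clip to an equal share of the panel so the sets stay disjoint
            n = min(eff[mod].n_regions, len(nuc_panel) // max(n_nuc_effects, 1))
            if n < 1:
                raise UsageError("nucleosome panel too small for planted effects")
            take = nuc_order[cursor:cursor + n]
            cursor += n
            informative[mod] = sorted(nuc_panel[i].name for i in take)
    inf_sets = {m: set(v) for m, v in informative.items()}

    labels = ["cancer"] * config.n_cancer + ["control"] * config.n_control
    sample_ids = [f"{lab}_{i:03d}" for i, lab in enumerate(labels)]
    sheet = pd.DataFrame({"sample_id": sample_ids, "label": labels,
                          "cohort": "sim"})

    fragments: dict[str, FragmentSet] = {}
    methylation: dict[str, pd.DataFrame] = {}
    lambda_calls: dict[str, pd.DataFrame] = {}
    for i, (sid, lab) in enumerate(zip(sample_ids, labels)):
        srng = np.random.default_rng(derive_seed(seed, 100, i))
        cancer = lab == "cancer"
        depth_factor = float(np.exp(srng.normal(0.0, config.depth_cv)))
        u_meth = float(srng.normal(0.0, config.meth_sample_sd))
        u_ndr = float(srng.normal(0.0, config.ndr_sample_sd))
        u_jit = float(srng.normal(0.0, config.jitter_sample_sd))

        all_s, all_e = [], []
        for region in nuc_panel:
            ndr = config.ndr_depth
            if cancer and region.name in inf_sets["occupancy"]:
                ndr = eff["occupancy"].value
            jit = config.jitter_sd
            if cancer and region.name in inf_sets["fuzziness"]:
                jit = eff["fuzziness"].value
            flm = None
            if cancer and region.name in inf_sets["wps"]:
                flm = eff["wps"].value
            s, e = simulate_region_fragments(
                region, srng, depth=config.depth * depth_factor,
                jitter_sd=max(0.0, jit + u_jit),
                ndr_depth=float(np.clip(ndr + u_ndr, 0.02, 1.0)),
                config=config, frag_len_mean=flm)
            all_s.append(s)
            all_e.append(e)
        starts = np.concatenate(all_s) if all_s else np.empty(0, np.int64)
        ends = np.concatenate(all_e) if all_e else np.empty(0, np.int64)
        fragments[sid] = FragmentSet(np.full(len(starts), "chr1", dtype=object),
                                     starts, ends, sample_id=sid)

        tables = []
        for region in meth_panel:
            rate = config.meth_rate
            if cancer and region.name in inf_sets["methylation"]:
                rate = eff["methylation"].value
            tables.append(simulate_methylation(
                cpg_positions(region, config.n_cpg_per_region), region.chrom,
                float(np.clip(rate + u_meth, 0.01, 0.99)),
                config.meth_coverage * depth_factor, srng))
        methylation[sid] = pd.concat(tables, ignore_index=True)

        lam_pos = 100 + 10 * np.arange(config.lambda_sites)
        lambda_calls[sid] = simulate_methylation(
            lam_pos, LAMBDA_CONTIG, 1.0 - config.lambda_conversion,
            config.lambda_coverage, srng)

    ground_truth = {
        "informative_regions": informative,
        "effects": {m: dataclasses.asdict(e) for m, e in eff.items()},
        "baselines": {"methylation": config.meth_rate,
                      "occupancy": config.ndr_depth,
                      "fuzziness": config.jitter_sd,
                      "wps": config.frag_len_mean},
        "seed": seed,
    }
    return SyntheticCohort(config, meth_panel, nuc_panel, sheet, fragments,
                           methylation, lambda_calls, ground_truth)
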