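"""Seeded generators for every input the pipeline consumes, with manifests.

Each generator emulates one arm of the study design:

* :func:`generate_regulatory_genome` — per-gene chromosomes with a known
  number of XBP1-consensus instances planted inside and outside accessible
  promoter chromatin, so motif counting has an exact ground truth;
* :func:`generate_ct_table` — replicated qPCR Ct tables with planted
  ddCt shifts and Gaussian technical noise, reference genes unshifted;
* :func:`generate_de_tables` — spliced/unspliced induction DE tables with
  planted up/down sets (345/199 by default, the scale of the XBP1s screen);
* :func:`generate_profile_matrix` — validated-panel-shaped fold-change
  matrices with planted activated / repressed / model-dependent genes.

Background sequence is uniform over ACGT; chromosomes whose scan does not
reproduce the planted counts exactly (chance background matches, or planted
instances spawning extra overlapping matches) are rejected and resampled,
so genome manifests are exact rather than probabilistic. Every generator
finishes by re-checking its own output against the manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import PROFILE_COLUMNS, REFERENCE_GENE
from .errors import InfeasiblePackingError, XbpTargetsError
from .intervals import GenomicInterval, TSSAnnotation, promoter_window
from .motifs import (
    IUPAC_CODES,
    IUPACMotif,
    XBP1_CONSENSUS,
    reverse_complement,
    scan_iupac,
)

#: Reference profile used for synthetic matrices (XBP1s's own fold changes
#: under induction, Tg, Tg+siXBP1, Tm, Tm+siXBP1 and the derived ratios).
REFERENCE_PROFILE = {
    "induced_xbp1s": 8.73,
    "tg_vs_ctrl": 10.60,
    "tg_sixbp1_vs_ctrl": 2.20,
    "tg_sixbp1_vs_tg": 0.21,
    "tm_vs_ctrl": 15.21,
    "tm_sixbp1_vs_ctrl": 1.46,
    "tm_sixbp1_vs_tm": 0.10,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's magnitudes as defaults."""

    seed: int = 0

    # regulatory genome
    n_genes: int = 20
    flank_up: int = 10_000
    flank_down: int = 10_000
    margin: int = 500  # unsearched chromosome padding beyond the window
    motif: str = XBP1_CONSENSUS
    accessible_per_gene: int = 4
    inaccessible_per_gene: int = 3
    open_fraction: float = 0.2
    n_open_blocks: int = 4

    # qPCR
    ct_noise_sd: float = 0.1
    n_experiments: int = 3
    n_technical: int = 3
    induction_fold: float = 11.0  # XBP1s induction magnitude in the cell line
    n_ct_genes: int = 10
    n_ct_null_genes: int = 0
    reference_genes: tuple[str, str] = ("GAPDH", "RPLP0")

    # differential expression
    n_de_genes: int = 12_000
    n_spliced_up: int = 345
    n_spliced_down: int = 199
    n_unspliced_up: int = 120
    n_unspliced_down: int = 80
    n_shared: int = 25  # genes affected in both induction systems
    null_lfc_sd: float = 0.3
    planted_lfc_mean: float = 2.0
    planted_lfc_sd: float = 0.5
    planted_p_beta: tuple[float, float] = (0.5, 20.0)
    enforce_margins: bool = True
    de_min_abs_log2fc: float = 1.0
    de_max_p: float = 0.05

    # profile matrix
    n_profile_repressed: int = 25
    n_profile_activated: int = 25
    n_profile_model_dependent: int = 10
    n_profile_null: int = 440
    profile_noise_sd: float = 0.10  # sd of ln(fold change)
    silencing_ratio: float = 2.0  # planted repressed silencing-vs-stress ratio
    induction_ratio: float = 0.5  # planted repressed induced-XBP1s fold
    stress_fold: float = 2.0  # stress-vs-ctrl fold for planted genes

    def __post_init__(self) -> None:
        if not 0 < self.open_fraction < 1:
            raise XbpTargetsError("open_fraction must be in (0, 1)")
        if self.ct_noise_sd < 0:
            raise XbpTargetsError("ct_noise_sd must be >= 0")
        for name in (
            "n_genes",
            "accessible_per_gene",
            "inaccessible_per_gene",
            "n_de_genes",
        ):
            if getattr(self, name) < 0:
                raise XbpTargetsError(f"{name} must be >= 0")


# --- regulatory genome ---------------------------------------------------

@dataclass(frozen=True)
class GenomeManifest:
    """Ground truth for a simulated regulatory genome."""

    motif: str
    accessible_counts: dict[str, int]
    inaccessible_counts: dict[str, int]
    rejections: int  # chromosomes resampled due to chance matches


def _concrete_instance(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(sorted(IUPAC_CODES[c])) if len(IUPAC_CODES[c]) > 1 else next(iter(IUPAC_CODES[c]))
        for c in pattern
    )


def _place_disjoint(
    regions: list[tuple[int, int]],
    n: int,
    length: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
) -> list[int]:
    """Sample ``n`` disjoint start positions of ``length`` inside ``regions``."""
    slots = [(s, e) for s, e in regions if e - s >= length]
    capacity = sum(e - s - length + 1 for s, e in slots)
    if capacity < n * (2 * length):  # crude feasibility guard
        raise InfeasiblePackingError(
            f"cannot place {n} instances of length {length} in {len(regions)} regions"
        )
    starts: list[int] = []
    attempts = 0
    while len(starts) < n:
        attempts += 1
        if attempts > 200 * n + 200:
            raise InfeasiblePackingError(
                f"failed to place {n} instances of length {length} after {attempts} draws"
            )
        s0, e0 = slots[rng.integers(len(slots))]
        pos = int(rng.integers(s0, e0 - length + 1))
        if all(pos + length <= a or pos >= b for a, b in occupied):
            starts.append(pos)
            occupied.append((pos, pos + length))
    return sorted(starts)


def generate_regulatory_genome(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, str], list[GenomicInterval], list[TSSAnnotation], GenomeManifest]:
    """One chromosome per gene with planted motif instances.

    Each gene sits on its own chromosome with the TSS at the centre of a
    symmetric window; ``n_open_blocks`` accessible blocks covering
    ``open_fraction`` of the window carry ``accessible_per_gene`` planted
    instances, and ``inaccessible_per_gene`` instances land in the closed
    gaps. Rescanning the emitted genome reproduces the manifest exactly.
    """
    rng = np.random.default_rng([config.seed, 101])
    motif = IUPACMotif(config.motif)
    k = len(motif)
    window_len = config.flank_up + config.flank_down
    chrom_length = window_len + 2 * config.margin
    w_start, w_end = config.margin, config.margin + window_len

    block_len = int(config.open_fraction * window_len / config.n_open_blocks)
    if block_len < k + 2:
        raise InfeasiblePackingError(
            "open-chromatin blocks shorter than the motif; raise open_fraction "
            "or lower n_open_blocks"
        )

    genome: dict[str, str] = {}
    open_chromatin: list[GenomicInterval] = []
    annotations: list[TSSAnnotation] = []
    acc_counts: dict[str, int] = {}
    inacc_counts: dict[str, int] = {}
    rejections = 0

    for g in range(config.n_genes):
        gene_id = f"gene_{g:04d}"
        chrom = f"chr_{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        # TSS placed so the strand-aware window is exactly [w_start, w_end)
        tss_pos = w_start + (config.flank_up if strand == "+" else config.flank_down)
        # accessible blocks: one per equal slot of the window, random offset,
        # >= 1 bp away from slot edges so merged blocks stay disjoint
        slot = window_len // config.n_open_blocks
        blocks: list[tuple[int, int]] = []
        for b in range(config.n_open_blocks):
            lo = w_start + b * slot + 1
            hi = w_start + (b + 1) * slot - block_len - 1
            if hi < lo:
                raise InfeasiblePackingError("window too small for requested blocks")
            s = int(rng.integers(lo, hi + 1))
            blocks.append((s, s + block_len))
        gaps = []
        prev = w_start
        for s, e in blocks:
            if s - prev >= k:
                gaps.append((prev, s))
            prev = e
        if w_end - prev >= k:
            gaps.append((prev, w_end))

        for _attempt in range(60):
            occupied: list[tuple[int, int]] = []
            acc_starts = _place_disjoint(blocks, config.accessible_per_gene, k, rng, occupied)
            inacc_starts = _place_disjoint(gaps, config.inaccessible_per_gene, k, rng, occupied)
            seq = rng.choice(list("ACGT"), size=chrom_length)
            for pos in acc_starts + inacc_starts:
                inst = _concrete_instance(motif.pattern, rng)
                if rng.random() < 0.5:
                    inst = reverse_complement(inst)
                seq[pos : pos + k] = list(inst)
            seq_str = "".join(seq)
            hits = scan_iupac(seq_str, motif, both_strands=True, chrom=chrom)
            in_block = [
                h for h in hits if any(s <= h.start and h.end <= e for s, e in blocks)
            ]
            planted_found = {h.start for h in hits} == set(acc_starts) | set(inacc_starts)
            if (
                planted_found
                and len(hits) == config.accessible_per_gene + config.inaccessible_per_gene
                and len(in_block) == config.accessible_per_gene
            ):
                break
            rejections += 1
        else:
            raise InfeasiblePackingError(
                f"{gene_id}: could not realize planted counts in 60 attempts"
            )

        genome[chrom] = seq_str
        open_chromatin.extend(GenomicInterval(chrom, s, e) for s, e in blocks)
        annotations.append(TSSAnnotation(gene_id, chrom, tss_pos, strand))
        acc_counts[gene_id] = config.accessible_per_gene
        inacc_counts[gene_id] = config.inaccessible_per_gene

    manifest = GenomeManifest(motif.pattern, acc_counts, inacc_counts, rejections)
    _verify_genome(config, genome, open_chromatin, annotations, manifest)
    if out_dir is not None:
        from . import io as xio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        xio.write_fasta(genome, out / "genome.fa")
        xio.write_bed(open_chromatin, out / "open_chromatin.bed")
        xio.write_tss_table(annotations, out / "tss.tsv")
        rows = [
            f"{g}\t{acc_counts[g]}\t{inacc_counts[g]}" for g in sorted(acc_counts)
        ]
        (out / "genome_manifest.tsv").write_text(
            "gene_id\taccessible\tinaccessible\n" + "\n".join(rows) + "\n"
        )
    return genome, open_chromatin, annotations, manifest


def _verify_genome(config, genome, open_chromatin, annotations, manifest) -> None:
    """Self-check: rescanning the output reproduces the manifest exactly."""
    from .motifs import count_motifs_per_gene

    windows = [
        promoter_window(a, config.flank_up, config.flank_down, len(genome[a.chrom]))
        for a in annotations
    ]
    reports = count_motifs_per_gene(genome, windows, open_chromatin, manifest.motif)
    for rep in reports:
        if rep.n_hits != manifest.accessible_counts[rep.gene_id]:
            raise XbpTargetsError(
                f"generator self-check failed for {rep.gene_id}: "
                f"{rep.n_hits} != {manifest.accessible_counts[rep.gene_id]}"
            )


# --- Ct tables -----------------------------------------------------------

@dataclass(frozen=True)
class CtManifest:
    """Planted ddCt (and equivalent fold change) per gene and condition."""

    ddct: dict[str, dict[str, float]]  # condition -> gene -> planted ddCt
    baseline_condition: str
    noise_sd: float


def generate_ct_table(
    config: SimulationConfig,
    conditions: dict[str, dict[str, float]] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, CtManifest]:
    """Replicated Ct table with planted ddCt shifts.

    ``conditions`` maps condition id to ``{gene: planted ddCt}``; the default
    is a single ``induced`` condition shifting ``n_ct_genes`` target genes by
    -log2(induction_fold) (an 11-fold induction by default) and leaving
    ``n_ct_null_genes`` null genes unshifted. Reference genes carry no shift.
    Each gene is measured in its own sample (one plate per gene), so genes
    are statistically independent; noise model per well:
    ``Ct = gene baseline + ddCt + Normal(0, ct_noise_sd)``.
    """
    rng = np.random.default_rng([config.seed, 202])
    if conditions is None:
        effect = -math.log2(config.induction_fold)
        genes = {f"target_{i:04d}": effect for i in range(config.n_ct_genes)}
        genes.update({f"null_{i:04d}": 0.0 for i in range(config.n_ct_null_genes)})
        conditions = {"induced": genes}
    all_genes = sorted({g for eff in conditions.values() for g in eff})
    base_ct = {g: float(rng.uniform(18, 30)) for g in all_genes}
    ref_base = {r: float(rng.uniform(15, 20)) for r in config.reference_genes}

    rows = []
    cond_ids = ["ctrl", *conditions.keys()]
    for gene in all_genes:
        sample = f"sample_{gene}"
        for cond in cond_ids:
            shift = conditions.get(cond, {}).get(gene, 0.0)
            for e in range(1, config.n_experiments + 1):
                for t in range(1, config.n_technical + 1):
                    noise = float(rng.normal(0, config.ct_noise_sd)) if config.ct_noise_sd else 0.0
                    rows.append(
                        (sample, cond, gene, e, t, base_ct[gene] + shift + noise)
                    )
                    for ref in config.reference_genes:
                        noise = (
                            float(rng.normal(0, config.ct_noise_sd))
                            if config.ct_noise_sd
                            else 0.0
                        )
                        rows.append((sample, cond, ref, e, t, ref_base[ref] + noise))
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "condition_id", "gene_id", "experiment", "technical", "ct"],
    )
    manifest = CtManifest(
        ddct={c: dict(eff) for c, eff in conditions.items()},
        baseline_condition="ctrl",
        noise_sd=config.ct_noise_sd,
    )
    _verify_ct(config, table, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "ct_table.tsv", sep="\t", index=False)
        with open(out / "ct_manifest.tsv", "w") as fh:
            fh.write("condition_id\tgene_id\tddct\tfold_change\n")
            for cond, eff in manifest.ddct.items():
                for g, d in sorted(eff.items()):
                    fh.write(f"{cond}\t{g}\t{d}\t{2.0 ** -d}\n")
    return table, manifest


def _verify_ct(config, table, manifest) -> None:
    """Noise-free tables must recover planted fold changes exactly."""
    if config.ct_noise_sd != 0:
        return
    from .qpcr import delta_delta_ct

    for cond, effects in manifest.ddct.items():
        for gene, ddct in effects.items():
            sub = table[table["sample_id"] == f"sample_{gene}"]
            rel = delta_delta_ct(sub, gene, cond, manifest.baseline_condition)
            if abs(rel.delta_delta_ct - ddct) > 1e-9:
                raise XbpTargetsError(
                    f"generator self-check failed for {gene}/{cond}: "
                    f"{rel.delta_delta_ct} != {ddct}"
                )


# --- DE tables -----------------------------------------------------------

@dataclass(frozen=True)
class DEManifest:
    """Planted set structure of a spliced/unspliced DE table pair."""

    spliced_up: frozenset[str]
    spliced_down: frozenset[str]
    unspliced_up: frozenset[str]
    unspliced_down: frozenset[str]
    xbp1s_only_up: frozenset[str]
    xbp1s_only_down: frozenset[str]
    margins_enforced: bool


def _de_table(
    genes: list[str],
    up: frozenset[str],
    down: frozenset[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    a, b = config.planted_p_beta
    thr, max_p = config.de_min_abs_log2fc, config.de_max_p
    lfc = rng.normal(0, config.null_lfc_sd, size=len(genes))
    pvals = rng.uniform(0, 1, size=len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    for gene_set, sign in ((up, 1.0), (down, -1.0)):
        for g in gene_set:
            i = idx[g]
            val = rng.normal(sign * config.planted_lfc_mean, config.planted_lfc_sd)
            p = float(rng.beta(a, b))
            if config.enforce_margins:
                # resample until the planted effect clears the selection
                # thresholds with margin, so recovery is exact by design
                while abs(val) < 1.1 * thr or val * sign < 0:
                    val = rng.normal(sign * config.planted_lfc_mean, config.planted_lfc_sd)
                while p >= 0.9 * max_p:
                    p = float(rng.beta(a, b))
            lfc[i] = val
            pvals[i] = p
    if config.enforce_margins:
        planted = up | down
        for i, g in enumerate(genes):
            # keep null genes clear of the selection boundary
            if g not in planted and abs(lfc[i]) >= 0.9 * thr and pvals[i] < 1.2 * max_p:
                pvals[i] = float(rng.uniform(1.2 * max_p, 1.0))
    q = np.minimum(pvals * 2.0, 1.0)  # placeholder monotone FDR column
    return pd.DataFrame(
        {"gene_id": genes, "log2_fold_change": lfc, "p_value": pvals, "q_value": q}
    )


def generate_de_tables(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, DEManifest]:
    """Spliced and unspliced induction DE tables with planted sets.

    ``n_shared`` of the spliced-affected genes are also planted in the
    unspliced experiment (same direction), emulating induction-system
    artifacts that the control subtraction must remove. With
    ``enforce_margins`` (default) every planted effect clears the selection
    thresholds and every null gene stays clear of them, so threshold
    selection plus control subtraction recovers the planted XBP1s-only sets
    exactly; without it, the manifest is the planting intent and misses are
    quantified by the raw distributions.
    """
    rng = np.random.default_rng([config.seed, 303])
    n_planted = (
        config.n_spliced_up
        + config.n_spliced_down
        + config.n_unspliced_up
        + config.n_unspliced_down
    )
    if n_planted > config.n_de_genes:
        raise XbpTargetsError("planted set sizes exceed n_de_genes")
    genes = [f"g{i:06d}" for i in range(config.n_de_genes)]
    perm = rng.permutation(config.n_de_genes)
    pos = 0

    def take(n: int) -> frozenset[str]:
        nonlocal pos
        out = frozenset(genes[i] for i in perm[pos : pos + n])
        pos += n
        return out

    s_up = take(config.n_spliced_up)
    s_down = take(config.n_spliced_down)
    u_up_own = take(config.n_unspliced_up)
    u_down_own = take(config.n_unspliced_down)
    # shared genes: drawn from the spliced sets, planted in the unspliced
    # experiment too (same direction)
    n_shared = min(config.n_shared, len(s_up) + len(s_down))
    shared_pool = sorted(s_up) + sorted(s_down)
    shared = frozenset(
        shared_pool[i] for i in rng.choice(len(shared_pool), size=n_shared, replace=False)
    )
    u_up = u_up_own | (shared & s_up)
    u_down = u_down_own | (shared & s_down)

    spliced = _de_table(genes, s_up, s_down, config, rng)
    unspliced = _de_table(genes, u_up, u_down, config, rng)
    manifest = DEManifest(
        spliced_up=s_up,
        spliced_down=s_down,
        unspliced_up=u_up,
        unspliced_down=u_down,
        xbp1s_only_up=s_up - (u_up | u_down),
        xbp1s_only_down=s_down - (u_up | u_down),
        margins_enforced=config.enforce_margins,
    )
    if config.enforce_margins:
        _verify_de(config, spliced, unspliced, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spliced.to_csv(out / "de_spliced.tsv", sep="\t", index=False)
        unspliced.to_csv(out / "de_unspliced.tsv", sep="\t", index=False)
        with open(out / "de_manifest.tsv", "w") as fh:
            fh.write("set\tgene_id\n")
            for name in (
                "spliced_up",
                "spliced_down",
                "unspliced_up",
                "unspliced_down",
                "xbp1s_only_up",
                "xbp1s_only_down",
            ):
                for g in sorted(getattr(manifest, name)):
                    fh.write(f"{name}\t{g}\n")
    return spliced, unspliced, manifest


def _verify_de(config, spliced, unspliced, manifest) -> None:
    from .expression import select_de, subtract_control

    s_up, s_down = select_de(spliced, config.de_min_abs_log2fc, config.de_max_p)
    u_up, u_down = select_de(unspliced, config.de_min_abs_log2fc, config.de_max_p)
    part = subtract_control(s_up, s_down, u_up, u_down)
    if (
        part.xbp1s_only_up.members != manifest.xbp1s_only_up
        or part.xbp1s_only_down.members != manifest.xbp1s_only_down
    ):
        raise XbpTargetsError("generator self-check failed: DE sets not recovered")


# --- profile matrices ----------------------------------------------------

@dataclass(frozen=True)
class ProfileManifest:
    """Planted class per gene of a synthetic validated-panel matrix."""

    true_class: dict[str, str]


def generate_profile_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ProfileManifest]:
    """Fold-change + significance matrices with planted dependency classes.

    Planted repressed genes fall on induction (``induction_ratio``) and rise
    on silencing under both stressors (``silencing_ratio``); activated genes
    mirror them; model-dependent genes carry opposite-direction silencing
    ratios under Tg and Tm; null genes sit at fold change 1 everywhere.
    Every cell is backed by ``n_experiments`` simulated log-scale replicates
    (sd ``profile_noise_sd`` on the natural log), the displayed fold change
    is their exponentiated mean, and the significance flag is a Student's
    t-test of those replicates against the matching baseline replicates —
    so null cells flag at the test's false-positive rate.
    """
    from scipy import stats as _stats

    rng = np.random.default_rng([config.seed, 404])
    sd = config.profile_noise_sd
    ne = config.n_experiments
    sr, ir, sf = config.silencing_ratio, config.induction_ratio, config.stress_fold

    def true_profile(cls: str) -> dict[str, float]:
        if cls == "null":
            return {c: 1.0 for c in PROFILE_COLUMNS}
        if cls == "repressed":
            tg_ratio = tm_ratio = sr
            induced = ir
        elif cls == "activated":
            tg_ratio = tm_ratio = 1.0 / sr
            induced = 1.0 / ir
        else:  # model_dependent
            tg_ratio, tm_ratio = sr, 1.0 / sr
            induced = 1.0
        return {
            "induced_xbp1s": induced,
            "tg_vs_ctrl": sf,
            "tg_sixbp1_vs_ctrl": sf * tg_ratio,
            "tg_sixbp1_vs_tg": tg_ratio,
            "tm_vs_ctrl": sf,
            "tm_sixbp1_vs_ctrl": sf * tm_ratio,
            "tm_sixbp1_vs_tm": tm_ratio,
        }

    classes = (
        ["repressed"] * config.n_profile_repressed
        + ["activated"] * config.n_profile_activated
        + ["model_dependent"] * config.n_profile_model_dependent
        + ["null"] * config.n_profile_null
    )
    n = len(classes)
    genes = [f"pg_{i:04d}" for i in range(n)]

    # the three experimental approaches (induction, silencing under Tg,
    # silencing under Tm) are independent experiments, each with its own
    # vehicle control replicates; within an arm the vs-control and vs-stress
    # comparisons share the silencing replicates, as on a real plate
    measured = [
        ("induced_xbp1s", "ind"),
        ("tg_vs_ctrl", "tg"),
        ("tg_sixbp1_vs_ctrl", "tg"),
        ("tm_vs_ctrl", "tm"),
        ("tm_sixbp1_vs_ctrl", "tm"),
    ]
    ln_true = {
        col: np.array([math.log(true_profile(c)[col]) for c in classes])
        for col, _ in measured
    }
    ctrls = {arm: rng.normal(0.0, sd, size=(n, ne)) for arm in ("ind", "tg", "tm")}
    reps = {
        col: rng.normal(ln_true[col][:, None], sd, size=(n, ne))
        for col, _ in measured
    }

    fc_cols: dict[str, np.ndarray] = {}
    sig_cols: dict[str, np.ndarray] = {}
    for col, arm in measured:
        fc_cols[col] = np.exp(reps[col].mean(axis=1) - ctrls[arm].mean(axis=1))
        pvals = _stats.ttest_ind(reps[col], ctrls[arm], axis=1, equal_var=True).pvalue
        sig_cols[col] = pvals <= 0.05
    for ratio_col, num, den in (
        ("tg_sixbp1_vs_tg", "tg_sixbp1_vs_ctrl", "tg_vs_ctrl"),
        ("tm_sixbp1_vs_tm", "tm_sixbp1_vs_ctrl", "tm_vs_ctrl"),
    ):
        fc_cols[ratio_col] = fc_cols[num] / fc_cols[den]
        pvals = _stats.ttest_ind(reps[num], reps[den], axis=1, equal_var=True).pvalue
        sig_cols[ratio_col] = pvals <= 0.05

    fc = pd.DataFrame(
        {c: fc_cols[c] for c in PROFILE_COLUMNS}, index=genes
    ).reindex(columns=PROFILE_COLUMNS)
    sig = pd.DataFrame(
        {c: sig_cols[c] for c in PROFILE_COLUMNS}, index=genes
    ).reindex(columns=PROFILE_COLUMNS)
    fc.loc[REFERENCE_GENE] = [REFERENCE_PROFILE[c] for c in PROFILE_COLUMNS]
    sig.loc[REFERENCE_GENE] = True
    manifest = ProfileManifest(dict(zip(genes, classes)))
    return fc, sig, manifest
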