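"""Synthetic genomes, annotations, expression tables and ortholog maps.

The generator reproduces the marginal statistical structure the analysis
assumes, so every pipeline stage is testable without genome downloads:

* TSS windows drawn from a two-component (bimodal) nCpG mixture whose
  default components are LCP ~ N(0.120, 0.083^2) with weight 0.557 and
  HCP ~ N(0.631, 0.242^2) with weight 0.443 — the human promoter
  mixture; TTS windows from a single unimodal component.
* log2 expression positively coupled to promoter nCpG (coupling ``a``),
  with LCP genes given sparse Dirichlet tissue profiles (high tissue
  specificity) and a larger non-expressed fraction.
* a second organism whose nCpG targets drift by Gaussian noise (TSS and
  TTS drift SDs set separately) and whose expression divergence is
  coupled to the realized TSS dCpG with slope ``beta``.

Sequences are emitted by a first-order Markov chain over {A,C,G,T}: base
composition matches the GC target (split evenly between C and G) and the
C->G transition probability is tuned so the expected CpG rate equals
target_ncpg * (gc/2)^2. The realized nCpG of each emitted window — not
the target — is recorded in the truth table and drives the expression
coupling, so recovery tests are judged against what the sequence
actually contains. A fast values-only mode skips sequence emission and
models the finite-window measurement error as Gaussian noise instead.

All randomness flows from a single seed through deterministic substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numba
import numpy as np
import pandas as pd

from . import cpg

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)  # state order A,C,G,T
_C, _G = 1, 2


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    sd: float


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Mixture defaults are the human promoter nCpG components; drift SDs
    default to the distant-species pattern (TSS more conserved than TTS).
    """

    seed: int = 0
    n_genes: int = 2000
    half_width: int = 1500
    tissues: int = 6
    replicates: int = 2
    transcripts_per_gene: int = 1
    # promoter nCpG mixture (TSS) and unimodal terminator component (TTS)
    lcp_mix: MixtureComponent = field(default_factory=lambda: MixtureComponent(0.557, 0.120, 0.083))
    hcp_mix: MixtureComponent = field(default_factory=lambda: MixtureComponent(0.443, 0.631, 0.242))
    tts_mix: MixtureComponent = field(default_factory=lambda: MixtureComponent(1.0, 0.30, 0.10))
    gc_target: float = 0.5
    # expression model (log2 RPKM scale)
    expr_base: float = 3.0
    expr_coupling: float = 4.0  # a: log2 expression per unit nCpG
    gene_log2_sd: float = 2.0
    replicate_log2_sd: float = 0.25
    lcp_concentration: float = 0.3  # Dirichlet concentration: sparse profiles
    hcp_concentration: float = 5.0  # near-uniform profiles
    profile_floor: float = 0.1  # basal per-tissue level as a fraction of the total
    nonexpressed_frac_lcp: float = 0.08
    nonexpressed_frac_hcp: float = 0.02
    # divergence model (distant-species regime)
    divergence_beta: float = 1.0  # delta log2 expression per unit dCpG (TSS)
    divergence_noise_sd: float = 1.0
    tss_drift_sd: float = 0.15
    tts_drift_sd: float = 0.25
    transcript_jitter_sd: float = 0.03
    measurement_sd: float = 0.04  # values-only stand-in for window sampling noise
    genes_per_chromosome: int = 50

    def __post_init__(self) -> None:
        if abs(self.lcp_mix.weight + self.hcp_mix.weight - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for comp in (self.lcp_mix, self.hcp_mix, self.tts_mix):
            if comp.sd <= 0:
                raise ValueError("mixture sd must be positive")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")

    @property
    def max_feasible_ncpg(self) -> float:
        """Composition-preserving chains cap target nCpG at min(2, 2/gc)."""
        return min(2.0, 2.0 / self.gc_target)


# ---------------------------------------------------------------------------
# Sequence emission


@numba.njit(cache=False)
def _sample_chain(u: np.ndarray, cdf0: np.ndarray, cdf: np.ndarray) -> np.ndarray:  # pragma: no cover
    n = u.shape[0]
    states = np.empty(n, dtype=np.uint8)
    prev = np.uint8(0)
    for i in range(n):
        row = cdf0 if i == 0 else cdf[prev]
        x = u[i]
        s = np.uint8(0)
        while s < 3 and x > row[s]:
            s += np.uint8(1)
        states[i] = s
        prev = s
    return states


def _transition_matrix(target_ncpg: float, target_gc: float) -> tuple[np.ndarray, np.ndarray]:
    """Stationary composition pi and transition matrix P with pi P = pi and
    pi_C * P(C,G) = target_ncpg * (gc/2)^2.

    Rows for A and T draw iid from pi; the C row reserves mass q = target * gc/2
    for G; the G row absorbs the complementary column-balance terms so the
    stationary composition is exact. Feasibility (all entries in [0,1])
    requires target <= min(2, 2/gc).
    """
    s = target_gc / 2.0
    a = (1.0 - target_gc) / 2.0
    q = target_ncpg * s
    if q > min(1.0, 2.0 * s) + 1e-12:
        raise ValueError(
            f"target nCpG {target_ncpg} infeasible at GC {target_gc}: "
            f"feasible targets are <= min(2, 2/GC) = {min(2.0, 2.0 / target_gc):.2f}"
        )
    pi = np.array([a, s, s, a])
    P = np.tile(pi, (4, 1))
    w = np.array([a, s, 0.0, a])
    w /= w.sum()
    P[_C] = (1.0 - q) * w
    P[_C, _G] = q
    P[_G] = np.array([2 * a, 2 * s, 0.0, 2 * a]) - P[_C]
    P[_G, _G] = 2 * s - q
    return pi, P


def generate_promoter_sequence(
    target_ncpg: float,
    target_gc: float,
    length: int,
    rng: np.random.Generator,
) -> str:
    """Emit one window whose expected CpG rate matches the nCpG target.

    First-order Markov chain with the exact stationary composition
    (GC split evenly between C and G) and a C->G transition tuned so the
    CpG rate is target_ncpg * (gc/2)^2, so realized nCpG is unbiased for
    the target; a single 3 kb window still fluctuates around it with
    binomial sampling noise.
    """
    if not 0 <= target_ncpg:
        raise ValueError("target_ncpg must be nonnegative")
    pi, P = _transition_matrix(target_ncpg, target_gc)
    states = _sample_chain(rng.random(length), np.cumsum(pi), np.cumsum(P, axis=1))
    return _BASES[states].tobytes().decode("ascii")


def _random_filler(length: int, gc: float, rng: np.random.Generator) -> str:
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    states = rng.choice(4, size=length, p=pi).astype(np.uint8)
    return _BASES[states].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Latent gene table


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator, lo: float, hi: float
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def sample_gene_latents(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene classes, nCpG targets and strands for organism A."""
    n = config.n_genes
    hi = 0.98 * config.max_feasible_ncpg
    is_hcp = rng.random(n) < config.hcp_mix.weight
    tss = np.where(
        is_hcp,
        _truncated_normal(config.hcp_mix.mean, config.hcp_mix.sd, n, rng, 0.0, hi),
        _truncated_normal(config.lcp_mix.mean, config.lcp_mix.sd, n, rng, 0.0, hi),
    )
    tts = _truncated_normal(config.tts_mix.mean, config.tts_mix.sd, n, rng, 0.0, hi)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "true_class": np.where(is_hcp, "HCP", "LCP"),
            "tss_target": tss,
            "tts_target": tts,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )


def drift_latents(
    latents: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Organism B targets: A targets plus per-site Gaussian drift."""
    out = latents.copy()
    hi = 0.98 * config.max_feasible_ncpg
    out["tss_target"] = np.clip(
        out["tss_target"] + rng.normal(0.0, config.tss_drift_sd, len(out)), 0.0, hi
    )
    out["tts_target"] = np.clip(
        out["tts_target"] + rng.normal(0.0, config.tts_drift_sd, len(out)), 0.0, hi
    )
    out["gene_id"] = [g + "b" for g in latents["gene_id"]]
    return out


# ---------------------------------------------------------------------------
# Organism realization


@dataclass
class Organism:
    """One synthetic organism: genome, annotation and truth tables."""

    genome: dict[str, str] | None
    gtf: str | None
    transcript_truth: pd.DataFrame  # realized per-transcript nCpG
    gene_truth: pd.DataFrame  # gene-level realized nCpG + class


def _gene_truth_from_transcripts(transcript_truth: pd.DataFrame) -> pd.DataFrame:
    g = transcript_truth.groupby("gene_id", sort=True)
    out = g.agg(
        ncpg_tss=("ncpg_tss_real", "mean"),
        ncpg_tts=("ncpg_tts_real", "mean"),
        true_class=("true_class", "first"),
        n_transcripts=("transcript_id", "size"),
    ).reset_index()
    return out


def generate_organism(
    latents: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> Organism:
    """Realize genome FASTA + GTF for a latent gene table.

    Each transcript occupies its own block on a chromosome: a spacer, the
    3 kb site window nearest the chromosome start, an inter-site spacer,
    the second 3 kb window and a trailing spacer, so windows of different
    transcripts never overlap. On the plus strand the TSS window comes
    first; on the minus strand the TTS window does (TSS > TTS there).
    The realized nCpG of every emitted window is measured immediately and
    recorded as truth.
    """
    window = 2 * config.half_width
    spacer, inter = 200, 300
    block = spacer + window + inter + window + spacer
    chroms: dict[str, str] = {}
    gtf_lines: list[str] = []
    rows: list[dict] = []
    jitter_hi = 0.98 * config.max_feasible_ncpg

    chrom_parts: list[str] = []
    chrom_idx, in_chrom = 0, 0
    offset = 0

    def _flush() -> None:
        nonlocal chrom_parts, chrom_idx, in_chrom, offset
        if chrom_parts:
            chroms[f"chr{chrom_idx}"] = "".join(chrom_parts)
            chrom_idx += 1
        chrom_parts, in_chrom, offset = [], 0, 0

    for gene in latents.itertuples(index=False):
        for k in range(config.transcripts_per_gene):
            if in_chrom >= config.genes_per_chromosome * config.transcripts_per_gene:
                _flush()
            chrom = f"chr{chrom_idx}"
            tid = f"{gene.gene_id}.t{k}"
            if config.transcripts_per_gene > 1:
                tss_t = float(
                    np.clip(
                        gene.tss_target + rng.normal(0.0, config.transcript_jitter_sd),
                        0.0,
                        jitter_hi,
                    )
                )
                tts_t = float(
                    np.clip(
                        gene.tts_target + rng.normal(0.0, config.transcript_jitter_sd),
                        0.0,
                        jitter_hi,
                    )
                )
            else:
                tss_t, tts_t = float(gene.tss_target), float(gene.tts_target)

            seq_tss = generate_promoter_sequence(tss_t, config.gc_target, window, rng)
            seq_tts = generate_promoter_sequence(tts_t, config.gc_target, window, rng)
            first_seq, second_seq = (
                (seq_tss, seq_tts) if gene.strand == "+" else (seq_tts, seq_tss)
            )
            chrom_parts.append(_random_filler(spacer, config.gc_target, rng))
            chrom_parts.append(first_seq)
            chrom_parts.append(_random_filler(inter, config.gc_target, rng))
            chrom_parts.append(second_seq)
            chrom_parts.append(_random_filler(spacer, config.gc_target, rng))

            c1 = offset + spacer + config.half_width  # center of first window
            c2 = offset + spacer + window + inter + config.half_width
            tss_pos, tts_pos = (c1, c2) if gene.strand == "+" else (c2, c1)
            start0, end0 = min(tss_pos, tts_pos), max(tss_pos, tts_pos)
            gtf_lines.append(
                "\t".join(
                    [
                        chrom,
                        "cpgevo_sim",
                        "transcript",
                        str(start0 + 1),
                        str(end0 + 1),
                        ".",
                        gene.strand,
                        ".",
                        f'gene_id "{gene.gene_id}"; transcript_id "{tid}";',
                    ]
                )
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene.gene_id,
                    "true_class": gene.true_class,
                    "strand": gene.strand,
                    "chrom": chrom,
                    "tss_pos": tss_pos,
                    "tts_pos": tts_pos,
                    "tss_target": tss_t,
                    "tts_target": tts_t,
                    "ncpg_tss_real": cpg.ncpg_value(seq_tss),
                    "ncpg_tts_real": cpg.ncpg_value(seq_tts),
                }
            )
            offset += block
            in_chrom += 1
    _flush()
    transcript_truth = pd.DataFrame(rows)
    return Organism(
        genome=chroms,
        gtf="\n".join(gtf_lines) + "\n",
        transcript_truth=transcript_truth,
        gene_truth=_gene_truth_from_transcripts(transcript_truth),
    )


def realize_values_only(
    latents: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> Organism:
    """Values-only realization: targets plus Gaussian measurement noise.

    Stand-in for full sequence emission when only the downstream
    statistics matter; ``measurement_sd`` emulates the window-sampling
    noise of a measured 3 kb window.
    """
    n = len(latents)
    truth = pd.DataFrame(
        {
            "transcript_id": [f"{g}.t0" for g in latents["gene_id"]],
            "gene_id": latents["gene_id"].to_numpy(),
            "true_class": latents["true_class"].to_numpy(),
            "strand": latents["strand"].to_numpy(),
            "tss_target": latents["tss_target"].to_numpy(),
            "tts_target": latents["tts_target"].to_numpy(),
            "ncpg_tss_real": np.clip(
                latents["tss_target"] + rng.normal(0.0, config.measurement_sd, n), 0.0, None
            ),
            "ncpg_tts_real": np.clip(
                latents["tts_target"] + rng.normal(0.0, config.measurement_sd, n), 0.0, None
            ),
        }
    )
    return Organism(None, None, truth, _gene_truth_from_transcripts(truth))


# ---------------------------------------------------------------------------
# Expression realization


@dataclass
class ExpressionSim:
    raw: pd.DataFrame  # genes x samples RPKM
    sample_tissues: dict[str, str]
    total_log2: np.ndarray  # latent per-gene log2 total expression
    profiles: np.ndarray  # genes x tissues Dirichlet weights
    nonexpressed: np.ndarray  # boolean per gene


def generate_expression(
    gene_truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    total_log2: np.ndarray | None = None,
    profiles: np.ndarray | None = None,
    nonexpressed: np.ndarray | None = None,
) -> ExpressionSim:
    """Replicated RPKM table coupled to realized promoter nCpG.

    log2 total expression = base + a * nCpG_TSS + gene noise; a gene's
    tissue means modulate the total by a Dirichlet profile (sparse for
    LCP genes, near-uniform for HCP) mixed with a basal floor
    (``profile_floor``) so no tissue falls below a detectable fraction of
    the gene's level — a uniform profile leaves every tissue at the
    total. Replicates add Gaussian log2 noise. A class-dependent fraction
    of genes is non-expressed (all-zero rows).
    Pass ``total_log2``/``profiles``/``nonexpressed`` to reuse another
    organism's latents (ortholog realization).
    """
    n = len(gene_truth)
    n_t = config.tissues
    classes = gene_truth["true_class"].to_numpy()
    if total_log2 is None:
        total_log2 = (
            config.expr_base
            + config.expr_coupling * gene_truth["ncpg_tss"].to_numpy()
            + rng.normal(0.0, config.gene_log2_sd, n)
        )
    if profiles is None:
        conc = np.where(classes == "HCP", config.hcp_concentration, config.lcp_concentration)
        profiles = np.vstack([rng.dirichlet(np.full(n_t, c)) for c in conc])
    if nonexpressed is None:
        p_zero = np.where(
            classes == "HCP", config.nonexpressed_frac_hcp, config.nonexpressed_frac_lcp
        )
        nonexpressed = rng.random(n) < p_zero

    scale = (1.0 - config.profile_floor) * profiles * n_t + config.profile_floor
    tissue_means = (2.0 ** total_log2)[:, None] * scale
    samples, sample_tissues = [], {}
    cols = {}
    for t in range(n_t):
        for r in range(config.replicates):
            sid = f"tissue{t}_rep{r}"
            sample_tissues[sid] = f"tissue{t}"
            noise = 2.0 ** rng.normal(0.0, config.replicate_log2_sd, n)
            cols[sid] = tissue_means[:, t] * noise
            samples.append(sid)
    raw = pd.DataFrame(cols, index=pd.Index(gene_truth["gene_id"], name="gene_id"))
    raw.loc[nonexpressed, :] = 0.0
    return ExpressionSim(raw, sample_tissues, total_log2, profiles, nonexpressed)


# ---------------------------------------------------------------------------
# Full bundle


@dataclass
class SyntheticBundle:
    """Two coupled organisms plus expression tables and the ortholog map."""

    config: SimulationConfig
    organism_a: Organism
    organism_b: Organism
    expression_a: ExpressionSim
    expression_b: ExpressionSim
    orthologs: pd.DataFrame  # columns gene_a, gene_b


def simulate_bundle(config: SimulationConfig, sequences: bool = True) -> SyntheticBundle:
    """Generate the full two-organism study from one seed.

    Organism B's nCpG targets drift from A's; its log2 expression totals
    equal A's minus beta * realized TSS dCpG plus noise, so up-regulation
    in A tracks CpG gain in A relative to B. Tissue profiles and the
    non-expressed mask are shared across the pair (orthologs keep their
    tissue identity).
    """
    root = np.random.default_rng(config.seed)
    r_lat, r_orga, r_orgb, r_expr, r_div = root.spawn(5)
    latents_a = sample_gene_latents(config, r_lat)
    latents_b = drift_latents(latents_a, config, r_lat)
    realize = generate_organism if sequences else realize_values_only
    org_a = realize(latents_a, config, r_orga)
    org_b = realize(latents_b, config, r_orgb)

    expr_a = generate_expression(org_a.gene_truth, config, r_expr)
    dcpg_tss = (
        org_a.gene_truth["ncpg_tss"].to_numpy() - org_b.gene_truth["ncpg_tss"].to_numpy()
    )
    total_b = (
        expr_a.total_log2
        - config.divergence_beta * dcpg_tss
        + r_div.normal(0.0, config.divergence_noise_sd, len(dcpg_tss))
    )
    expr_b = generate_expression(
        org_b.gene_truth,
        config,
        r_expr,
        total_log2=total_b,
        profiles=expr_a.profiles,
        nonexpressed=expr_a.nonexpressed,
    )
    orthologs = pd.DataFrame(
        {
            "gene_a": org_a.gene_truth["gene_id"].to_numpy(),
            "gene_b": org_b.gene_truth["gene_id"].to_numpy(),
        }
    )
    return SyntheticBundle(config, org_a, org_b, expr_a, expr_b, orthologs)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Serialize a bundle: FASTA + GTF per organism, TSVs, sample maps, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, org, expr in (
        ("orgA", bundle.organism_a, bundle.expression_a),
        ("orgB", bundle.organism_b, bundle.expression_b),
    ):
        if org.genome is not None:
            with open(out / f"{name}.fa", "w") as fh:
                for chrom, seq in org.genome.items():
                    fh.write(f">{chrom}\n")
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")
            (out / f"{name}.gtf").write_text(org.gtf)
        org.transcript_truth.to_csv(out / f"{name}.truth.tsv", sep="\t", index=False)
        expr.raw.to_csv(out / f"{name}.rpkm.tsv", sep="\t")
        (out / f"{name}.samples.json").write_text(json.dumps(expr.sample_tissues, indent=1))
    bundle.orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False)


def config_with(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """A copy of ``config`` with fields replaced (dataclasses.replace shim)."""
    return replace(config, **kwargs)
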