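"""Synthetic allopolyploid transcriptomes with known ground truth.

Emulates the experimental design the pipeline targets: two diploid
parental species — maternal R and paternal C — an F1 diploid hybrid and an
F18 allotetraploid, three biological replicates each, with orthologous
gene pairs separated by fixed diagnostic SNPs.  Every downstream stage
(DE calling, ELD categories, homoeologue binning, HEB states, silencing
and novel expression, MPV trajectories, qPCR) can be exercised against the
recorded truth without any external data.

Generative model
----------------
* Gene lengths uniform over ``gene_length_range``; the C orthologue equals
  the R orthologue except at Bernoulli(``snp_rate``) substitution sites.
* Each gene carries a lognormal baseline weight and one programmed ELD
  category; the category fixes the relative expression multipliers of the
  R parent, C parent and hybrid total so that every relation the category
  declares significant is a true >= ``fold``-fold difference.
* Counts per replicate are negative-binomial (mean from the programmed
  multipliers scaled to ``depth`` expected reads per library, shared
  per-gene dispersion ``nb_dispersion``); the hybrid's two homoeologue
  components are a binomial split of the replicate's total count at the
  gene's programmed R mixing proportion, so both homoeologues share each
  replicate's biological noise.
* The hybrid mixing proportion realises the programmed HEB progeny state
  (``fold``-fold homoeologue bias, or 1:1); silencing sets it to 0 or 1,
  novel expression zeroes both parents.
* Reads are fixed-length, uniform-start, drawn from the homoeologue of
  origin and reported in SAM against the R transcript (coordinates are
  exact because the orthologues differ only by substitutions).  No
  sequencing errors are simulated by default, keeping binning truth exact.
* qPCR CT values are ``baseline - log2(expression) + N(0, sd)`` with
  triplicate technical replicates and an ``ND`` sentinel for silenced
  assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de_stats import CountMatrix
from .homoeolog import DiagnosticSnp, write_snp_table

__all__ = [
    "SimDesign",
    "Genomes",
    "CountBundle",
    "generate_genomes",
    "generate_counts",
    "generate_homoeolog_counts",
    "generate_reads",
    "generate_qpcr",
    "write_bundle",
    "DEFAULT_CATEGORY_MIX",
    "DEFAULT_HEB_MIX",
]

GROUPS = ("R", "C", "F1", "F18")
HYBRIDS = ("F1", "F18")
TISSUES = ("liver", "muscle", "ovary")
REFERENCE_ASSAY = "beta_actin"
_BASES = np.array(list("ACGT"))

#: programmed proportion of genes per ELD category ("conserved" = no change).
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "conserved": 0.70,
    "I": 0.01, "II": 0.01, "III": 0.01,
    "IV": 0.02, "V": 0.02, "VI": 0.02,
    "VII": 0.05, "VIII": 0.04, "IX": 0.05, "X": 0.04,
    "XI": 0.015, "XII": 0.015,
}

#: programmed proportions over (parental state, progeny state) HEB transitions,
#: patterned on the liver homoeologue table of the target study design.
DEFAULT_HEB_MIX: dict[tuple[str, str], float] = {
    ("R=C", "R=C"): 0.704,
    ("R>C", "R>C"): 0.042,
    ("R<C", "R<C"): 0.001,
    ("R>C", "R=C"): 0.084,
    ("R<C", "R=C"): 0.055,
    ("R=C", "R>C"): 0.065,
    ("R=C", "R<C"): 0.034,
    ("R<C", "R>C"): 0.001,
    ("R>C", "R<C"): 0.014,
}

#: per-category (R, C, hybrid) expression multipliers as powers of ``fold``.
#: transgressive and mid-parent categories space the parents fold^2 apart so
#: that every significant relation is at least a true fold-fold difference.
_CATEGORY_EXPONENTS: dict[str, tuple[float, float, float]] = {
    "conserved": (0, 0, 0),
    "I": (2, 1, 0),     # hybrid below both, R > C
    "II": (1, 1, 0),    # hybrid below both, R = C
    "III": (1, 2, 0),   # hybrid below both, R < C
    "IV": (0, 1, 2),    # hybrid above both, R < C
    "V": (0, 0, 1),     # hybrid above both, R = C
    "VI": (1, 0, 2),    # hybrid above both, R > C
    "VII": (0, 1, 1),   # hybrid at the higher C level
    "VIII": (1, 0, 0),  # hybrid at the lower C level
    "IX": (0, 1, 0),    # hybrid at the lower R level
    "X": (1, 0, 1),     # hybrid at the higher R level
    "XI": (0, 2, 1),    # mid-parent, R < C
    "XII": (2, 0, 1),   # mid-parent, R > C
}

_CATEGORY_PARENTAL_STATE: dict[str, str] = {
    cat: ("R>C" if er > ec else "R<C" if er < ec else "R=C")
    for cat, (er, ec, _) in _CATEGORY_EXPONENTS.items()
}


@dataclass
class SimDesign:
    """Parameters of one synthetic experiment.

    Defaults reproduce the study conditions the pipeline is validated
    under: 2,000 genes, four groups x three replicates, one million
    expected mapped reads per library, negative-binomial dispersion 0.05
    and four-fold programmed effects.
    """

    n_genes: int = 2000
    snp_rate: float = 0.01
    gene_length_range: tuple[int, int] = (500, 2000)
    n_replicates: int = 3
    depth: float = 1e6
    nb_dispersion: float = 0.05
    fold: float = 4.0
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    heb_mix: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_HEB_MIX)
    )
    silencing_fraction: float = 0.01
    novel_fraction: float = 0.005
    read_length: int = 100
    weight_sigma: float = 1.0          # lognormal spread of baseline expression
    ct_baseline: float = 35.0          # CT of one read-per-million equivalent
    ct_noise_sd: float = 0.15
    n_qpcr_genes: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.snp_rate <= 1:
            raise ValueError("snp_rate must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be positive and ordered")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name, mix in (("category_mix", self.category_mix), ("heb_mix", self.heb_mix)):
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions sum to {total}, not 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative proportions")
        unknown = set(self.category_mix) - set(_CATEGORY_EXPONENTS)
        if unknown:
            raise ValueError(f"unknown ELD categories in mix: {sorted(unknown)}")
        if self.silencing_fraction + self.novel_fraction > 1:
            raise ValueError("silencing + novel fractions exceed 1")

    def _rng(self, stream: int) -> np.random.Generator:
        # independent, order-insensitive substreams per generator stage
        return np.random.default_rng([int(self.seed), stream])

    @property
    def samples(self) -> dict[str, list[str]]:
        return {
            g: [f"{g}_{i + 1}" for i in range(self.n_replicates)] for g in GROUPS
        }


@dataclass
class Genomes:
    """Paired parental transcript sequences plus the diagnostic-SNP list."""

    genes: list[str]
    lengths: pd.Series
    seq_r: dict[str, str]
    seq_c: dict[str, str]
    snps: list[DiagnosticSnp]

    def snps_by_gene(self) -> dict[str, list[DiagnosticSnp]]:
        out: dict[str, list[DiagnosticSnp]] = {g: [] for g in self.genes}
        for s in self.snps:
            out[s.pair_id].append(s)
        return out

    def write_fasta(self, path_r: str | Path, path_c: str | Path) -> None:
        for path, seqs, genome in ((path_r, self.seq_r, "R"), (path_c, self.seq_c, "C")):
            records = [
                SeqRecord(Seq(seqs[g]), id=g, description=f"genome={genome}")
                for g in self.genes
            ]
            SeqIO.write(records, str(path), "fasta")


def generate_genomes(design: SimDesign) -> Genomes:
    """Orthologous R/C transcript pairs differing only at diagnostic SNPs."""
    design.validate()
    rng = design._rng(1)
    lo, hi = design.gene_length_range
    genes = [f"gene{i:05d}" for i in range(design.n_genes)]
    lengths = pd.Series(
        rng.integers(lo, hi + 1, size=design.n_genes), index=genes, name="length_bp"
    )
    seq_r: dict[str, str] = {}
    seq_c: dict[str, str] = {}
    snps: list[DiagnosticSnp] = []
    for g in genes:
        n = int(lengths[g])
        if n == 0:
            raise ValueError(f"zero-length gene {g}")
        base_idx = rng.integers(0, 4, size=n)
        r = _BASES[base_idx]
        c = r.copy()
        snp_sites = np.flatnonzero(rng.random(n) < design.snp_rate)
        for pos in snp_sites:
            # substitute with a uniformly chosen different base
            alt = (base_idx[pos] + rng.integers(1, 4)) % 4
            c[pos] = _BASES[alt]
            snps.append(DiagnosticSnp(g, int(pos), int(pos), str(r[pos]), str(c[pos])))
        seq_r[g] = "".join(r)
        seq_c[g] = "".join(c)
    return Genomes(genes, lengths, seq_r, seq_c, snps)


@dataclass
class CountBundle:
    """Counts, truth and the hybrid homoeologue components of one simulation."""

    count_matrix: CountMatrix
    truth: pd.DataFrame
    #: per hybrid sample: DataFrame(gene -> r_component, c_component)
    components: dict[str, pd.DataFrame]


def _sample_nb(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.clip(np.asarray(mean, dtype=float), 0.0, None)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def generate_counts(design: SimDesign, genomes: Genomes) -> CountBundle:
    """Replicate count matrices for R, C, F1 and F18 plus the truth table.

    Raises ``ValueError`` naming the genes that could not be assigned when
    the category and HEB mixtures are jointly unsatisfiable (a programmed
    parental relation whose HEB transitions all have zero probability).
    """
    design.validate()
    rng = design._rng(2)
    genes = genomes.genes
    n = len(genes)
    f = design.fold

    cats = list(design.category_mix)
    cat_p = np.array([design.category_mix[c] for c in cats], dtype=float)
    category = rng.choice(cats, size=n, p=cat_p / cat_p.sum())

    # HEB transition conditional on the category's parental relation
    parental = np.array([_CATEGORY_PARENTAL_STATE[c] for c in category])
    progeny = np.empty(n, dtype=object)
    unassignable: list[str] = []
    cond: dict[str, tuple[list[str], np.ndarray]] = {}
    for state in ("R>C", "R=C", "R<C"):
        opts = [(pr, p) for (pa, pr), p in design.heb_mix.items() if pa == state]
        states = [o[0] for o in opts]
        probs = np.array([o[1] for o in opts], dtype=float)
        cond[state] = (states, probs)
    for i, g in enumerate(genes):
        states, probs = cond[parental[i]]
        if probs.sum() <= 0:
            unassignable.append(g)
            continue
        progeny[i] = rng.choice(states, p=probs / probs.sum())
    if unassignable:
        raise ValueError(
            "category_mix and heb_mix are jointly unsatisfiable; could not "
            f"assign a HEB transition to genes: {unassignable[:20]}"
            + ("..." if len(unassignable) > 20 else "")
        )

    rho = np.where(
        progeny == "R>C", f / (1 + f), np.where(progeny == "R<C", 1 / (1 + f), 0.5)
    ).astype(float)

    # silencing / novel flags, drawn among genes programmed conserved so the
    # flags never contradict a programmed ELD or HEB effect
    r_sil = np.zeros(n, dtype=bool)
    c_sil = np.zeros(n, dtype=bool)
    novel = np.zeros(n, dtype=bool)
    conserved_idx = np.flatnonzero(
        (category == "conserved") & (progeny == "R=C")
    )
    n_sil = int(round(design.silencing_fraction * n))
    n_nov = int(round(design.novel_fraction * n))
    picked = rng.permutation(conserved_idx)[: n_sil + n_nov]
    sil_idx, nov_idx = picked[:n_sil], picked[n_sil:]
    half = len(sil_idx) // 2
    r_sil[sil_idx[:half]] = True
    c_sil[sil_idx[half:]] = True
    novel[nov_idx] = True
    rho[r_sil] = 0.0
    rho[c_sil] = 1.0
    progeny[r_sil] = "R<C"
    progeny[c_sil] = "R>C"

    weight = rng.lognormal(0.0, design.weight_sigma, size=n)
    expo = np.array([_CATEGORY_EXPONENTS[c] for c in category], dtype=float)
    mult_r = f ** expo[:, 0]
    mult_c = f ** expo[:, 1]
    mult_h = f ** expo[:, 2]
    mult_r[novel] = 0.0
    mult_c[novel] = 0.0

    # programmed relative expression, scaled by one shared normalizer so a
    # conserved gene has the same programmed mean in every group (library
    # totals then differ slightly with composition, as in real libraries)
    rel = {"R": weight * mult_r, "C": weight * mult_c}
    rel["F1"] = rel["F18"] = weight * mult_h
    shared = float(np.mean([rel[g].sum() for g in GROUPS]))
    means = {g: design.depth * rel[g] / shared for g in GROUPS}

    counts: dict[str, np.ndarray] = {}
    components: dict[str, pd.DataFrame] = {}
    for group in GROUPS:
        for sample in design.samples[group]:
            total = _sample_nb(rng, means[group], design.nb_dispersion)
            counts[sample] = total
            if group in HYBRIDS:
                r_comp = rng.binomial(total, rho)
                components[sample] = pd.DataFrame(
                    {"r_component": r_comp, "c_component": total - r_comp},
                    index=pd.Index(genes, name="gene"),
                )

    count_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"))
    lib_sizes = count_df.sum(axis=0).astype(float)
    groups = pd.Series(
        {s: g for g in GROUPS for s in design.samples[g]}, name="group"
    )
    cm = CountMatrix(count_df, genomes.lengths, lib_sizes, groups)

    snp_counts = {g: 0 for g in genes}
    for s in genomes.snps:
        snp_counts[s.pair_id] += 1
    truth = pd.DataFrame(
        {
            "category": category,
            "parental_state": parental,
            "progeny_state": progeny.astype(str),
            "transition": [
                "parental-condition" if pa == pr
                else "no-bias-in-progeny" if pr == "R=C"
                else "novel-bias-in-progeny"
                for pa, pr in zip(parental, progeny)
            ],
            "rho": rho,
            "r_silencing": r_sil,
            "c_silencing": c_sil,
            "novel_expression": novel,
            "mean_R": means["R"],
            "mean_C": means["C"],
            "mean_hybrid": means["F1"],
            "weight": weight,
            "length_bp": genomes.lengths.values,
            "n_snps": [snp_counts[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return CountBundle(cm, truth, components)


def _informative_probability(
    length: int, read_length: int, snp_positions: Sequence[int]
) -> float:
    """Probability a uniform-start read of fixed length covers >= 1 SNP."""
    n_starts = length - read_length + 1
    if n_starts <= 0 or not snp_positions:
        return 0.0
    covered: set[int] = set()
    for pos in snp_positions:
        lo = max(0, pos - read_length + 1)
        hi = min(n_starts - 1, pos)
        covered.update(range(lo, hi + 1))
    return len(covered) / n_starts


def generate_homoeolog_counts(
    design: SimDesign, genomes: Genomes, bundle: CountBundle
) -> pd.DataFrame:
    """Homoeologue-specific informative-read bins per hybrid sample.

    Binomially thins each homoeologue component by the exact per-gene
    probability that a read covers at least one diagnostic SNP — the same
    generative model :func:`generate_reads` realises read by read.
    Returns the long table ``pair_id, sample, r_count, c_count, ambiguous,
    r_per_million, c_per_million``.
    """
    rng = design._rng(3)
    snps = genomes.snps_by_gene()
    p_inf = np.array(
        [
            _informative_probability(
                int(genomes.lengths[g]),
                design.read_length,
                [s.pos_r for s in snps[g]],
            )
            for g in genomes.genes
        ]
    )
    rows = []
    for sample, comp in bundle.components.items():
        lib = float(bundle.count_matrix.library_sizes[sample])
        r_bin = rng.binomial(comp["r_component"].values, p_inf)
        c_bin = rng.binomial(comp["c_component"].values, p_inf)
        total = comp["r_component"].values + comp["c_component"].values
        for g, r, c, t in zip(genomes.genes, r_bin, c_bin, total):
            rows.append(
                {
                    "pair_id": g,
                    "sample": sample,
                    "r_count": int(r),
                    "c_count": int(c),
                    "ambiguous": int(t - r - c),
                    "r_per_million": 1e6 * r / lib,
                    "c_per_million": 1e6 * c / lib,
                }
            )
    return pd.DataFrame(rows)


def generate_reads(
    design: SimDesign,
    genomes: Genomes,
    bundle: CountBundle,
    outdir: str | Path,
    samples: Iterable[str] | None = None,
) -> dict[str, dict[str, Path]]:
    """FASTQ reads and SAM alignments for the hybrid libraries.

    Each hybrid read is drawn from its homoeologue of origin (the
    component counts of :func:`generate_counts`) at a uniform start
    position and reported against the R transcript as reference, with
    1-based SAM coordinates.  The true genome of origin is recorded in the
    read name (``<sample>:<gene>:<serial>:<R|C>``), making binning truth
    checkable read by read.
    """
    rng = design._rng(4)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rl = design.read_length
    too_short = [g for g in genomes.genes if genomes.lengths[g] < rl]
    if too_short:
        raise ValueError(
            f"read length {rl} exceeds gene length for: {too_short[:10]}"
        )
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": g, "LN": int(genomes.lengths[g])} for g in genomes.genes
        ],
    }
    paths: dict[str, dict[str, Path]] = {}
    if samples is None:
        samples = list(bundle.components)
    for sample in samples:
        comp = bundle.components[sample]
        sam_path = outdir / f"{sample}.sam"
        fq_path = outdir / f"{sample}.fastq"
        serial = 0
        with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam, open(
            fq_path, "w"
        ) as fq:
            for gi, g in enumerate(genomes.genes):
                length = int(genomes.lengths[g])
                for origin, n_reads in (
                    ("R", int(comp["r_component"].iloc[gi])),
                    ("C", int(comp["c_component"].iloc[gi])),
                ):
                    seq = genomes.seq_r[g] if origin == "R" else genomes.seq_c[g]
                    starts = rng.integers(0, length - rl + 1, size=n_reads)
                    for start in starts:
                        read_seq = seq[start : start + rl]
                        name = f"{sample}:{g}:{serial}:{origin}"
                        serial += 1
                        a = pysam.AlignedSegment(sam.header)
                        a.query_name = name
                        a.query_sequence = read_seq
                        a.flag = 0
                        a.reference_id = gi
                        a.reference_start = int(start)
                        a.mapping_quality = 60
                        a.cigartuples = [(0, rl)]
                        a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                        sam.write(a)
                        fq.write(f"@{name}\n{read_seq}\n+\n{'I' * rl}\n")
        paths[sample] = {"sam": sam_path, "fastq": fq_path}
    return paths


def generate_qpcr(
    design: SimDesign,
    bundle: CountBundle,
    genes: Sequence[str] | None = None,
    tissues: Sequence[str] = TISSUES,
) -> pd.DataFrame:
    """Long-format CT table for homoeologue-specific qPCR assays.

    One biological sample per group, triplicate technical replicates, with
    assays ``<gene>_R``, ``<gene>_C`` and the shared reference
    ``beta_actin``.  CT = baseline - log2(expression per million) + noise;
    a zero-expression homoeologue (parent lacking the other genome, or a
    programmed silencing) yields the ``ND`` sentinel.
    """
    rng = design._rng(5)
    truth = bundle.truth
    if genes is None:
        with_snps = truth.index[truth["n_snps"] > 0]
        genes = list(with_snps[: design.n_qpcr_genes])
    missing = [g for g in genes if g not in truth.index]
    if missing:
        raise KeyError(f"unknown genes for qPCR: {missing}")

    ref_expr = 5000.0  # per-million equivalent of the reference gene
    rows = []
    for tissue in tissues:
        for group in GROUPS:
            # per-million programmed expression of each homoeologue
            for g in genes:
                t = truth.loc[g]
                scale = 1e6 / design.depth
                if group == "R":
                    e = {"R": t["mean_R"] * scale, "C": 0.0}
                elif group == "C":
                    e = {"R": 0.0, "C": t["mean_C"] * scale}
                else:
                    e = {
                        "R": t["mean_hybrid"] * t["rho"] * scale,
                        "C": t["mean_hybrid"] * (1 - t["rho"]) * scale,
                    }
                for genome in ("R", "C"):
                    silenced = e[genome] <= 0
                    if silenced and group in HYBRIDS:
                        flagged = (
                            (genome == "R" and t["r_silencing"])
                            or (genome == "C" and t["c_silencing"])
                            or t["novel_expression"]
                        )
                        if not flagged:
                            raise ValueError(
                                f"gene {g}: non-positive {genome} homoeologue "
                                "expression without a silencing/novel flag"
                            )
                    for rep in range(1, 4):
                        if silenced:
                            ct = np.nan
                        else:
                            ct = (
                                design.ct_baseline
                                - np.log2(e[genome])
                                + rng.normal(0.0, design.ct_noise_sd)
                            )
                        rows.append(
                            {
                                "sample": group,
                                "tissue": tissue,
                                "assay": f"{g}_{genome}",
                                "replicate": rep,
                                "ct": ct,
                            }
                        )
            for rep in range(1, 4):
                rows.append(
                    {
                        "sample": group,
                        "tissue": tissue,
                        "assay": REFERENCE_ASSAY,
                        "replicate": rep,
                        "ct": design.ct_baseline
                        - np.log2(ref_expr)
                        + rng.normal(0.0, design.ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def write_bundle(
    design: SimDesign, outdir: str | Path, write_reads: bool = False
) -> dict[str, Path]:
    """Generate and write a full synthetic bundle to ``outdir``.

    Writes parental FASTA, the diagnostic-SNP table, the count matrix
    (counts/lengths/samples TSVs), the truth table, the homoeologue bin
    table and a CT table; SAM/FASTQ reads for the hybrid libraries are
    optional because read files grow with depth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes = generate_genomes(design)
    bundle = generate_counts(design, genomes)
    genomes.write_fasta(outdir / "R.fasta", outdir / "C.fasta")
    write_snp_table(genomes.snps, outdir / "snps.tsv")
    bundle.count_matrix.to_dir(outdir)
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t")
    homo = generate_homoeolog_counts(design, genomes, bundle)
    homo.to_csv(outdir / "homoeolog_counts.tsv", sep="\t", index=False)
    ct = generate_qpcr(design, bundle)
    from .qpcr import write_ct_table

    write_ct_table(ct, outdir / "ct_table.tsv")
    paths = {
        "fasta_r": outdir / "R.fasta",
        "fasta_c": outdir / "C.fasta",
        "snps": outdir / "snps.tsv",
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "lengths.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "homoeolog_counts": outdir / "homoeolog_counts.tsv",
        "ct_table": outdir / "ct_table.tsv",
    }
    if write_reads:
        read_paths = generate_reads(design, genomes, bundle, outdir / "reads")
        for sample, d in read_paths.items():
            paths[f"sam_{sample}"] = d["sam"]
    return paths
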