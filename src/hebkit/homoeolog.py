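"""Homoeologue-specific analysis from diagnostic SNPs.

In an interspecific hybrid the two gene copies descended from the maternal
(R) and paternal (C) genomes — the homoeologues — can be told apart at
fixed inter-genome sequence differences (diagnostic SNPs).  This module
covers the whole chain: reciprocal-best-hit orthologue pairing from BLAST
tabular hits, diagnostic-SNP discovery with parental concordance
validation, per-read homoeologue binning from SAM alignments by majority
vote over diagnostic sites, reads-per-million silencing / novel-expression
calls, and the homoeologue-expression-bias (HEB) state classifier that
compares the parental R-vs-C state with the R-vs-C homoeologue balance
inside each hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .de_stats import fisher_de

__all__ = [
    "OrthologuePair",
    "DiagnosticSnp",
    "find_orthologues",
    "find_diagnostic_snps",
    "bin_reads",
    "call_expression_status",
    "classify_heb",
    "classify_heb_table",
    "heb_transition",
    "HEB_STATES",
    "SILENCE_THRESHOLD_PER_MILLION",
]

HEB_STATES = ("R>C", "R=C", "R<C")
#: reads-homoeologue-per-million threshold below which a homoeologue is silent.
SILENCE_THRESHOLD_PER_MILLION = 10.0
#: per-comparison significance for the progeny homoeologue test (no FDR).
HEB_ALPHA = 0.05


# ---------------------------------------------------------------------------
# orthologue pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologuePair:
    r_id: str
    c_id: str
    aln_len: int
    evalue: float
    reciprocal: bool = True


def _best_hits(path: str | Path) -> dict[str, tuple[str, float, int]]:
    """Best subject per query from a 12-column BLAST tabular (outfmt 6) file.

    Best hit = lowest e-value, ties broken by longer alignment, then by
    lexicographically smaller subject id, so orthologue sets are
    reproducible.
    """
    best: dict[str, tuple[float, int, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated BLAST fields, "
                    f"got {len(fields)}"
                )
            try:
                query, subject = fields[0], fields[1]
                aln_len = int(fields[3])
                evalue = float(fields[10])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed hit row ({err})") from None
            key = (evalue, -aln_len, subject)
            if query not in best or key < best[query]:
                best[query] = key
    return {q: (subj, ev, -neg) for q, (ev, neg, subj) in best.items()}


def find_orthologues(
    hits_r_to_c: str | Path,
    hits_c_to_r: str | Path,
    evalue_max: float = 1e-20,
    min_aln_bp: int = 300,
) -> list[OrthologuePair]:
    """Reciprocal-best-hit orthologue pairs between the R and C transcript sets.

    A pair is retained when each sequence is the other's best BLASTN hit,
    the best hit's e-value is <= ``evalue_max`` and the alignment spans at
    least ``min_aln_bp``.
    """
    fwd = _best_hits(hits_r_to_c)
    rev = _best_hits(hits_c_to_r)
    pairs = []
    for r_id, (c_id, evalue, aln_len) in sorted(fwd.items()):
        back = rev.get(c_id)
        if back is None or back[0] != r_id:
            continue
        if evalue > evalue_max or aln_len < min_aln_bp:
            continue
        pairs.append(OrthologuePair(r_id, c_id, aln_len, evalue))
    return pairs


# ---------------------------------------------------------------------------
# diagnostic SNPs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticSnp:
    """A fixed R/C difference that assigns an overlapping read to a genome.

    Positions are 0-based on the respective transcript; the TSV writer
    emits them 1-based.
    """

    pair_id: str
    pos_r: int
    pos_c: int
    allele_r: str
    allele_c: str
    concordance_r: float = 1.0
    concordance_c: float = 1.0


def find_diagnostic_snps(
    pair_id: str,
    aln_r: str,
    aln_c: str,
    pileups: Mapping[tuple[str, int], Mapping[str, int]] | None = None,
    min_concordance: float = 0.9,
    min_cov: int = 5,
) -> list[DiagnosticSnp]:
    """Diagnostic SNPs from one pairwise transcript alignment.

    ``aln_r`` / ``aln_c`` are the aligned sequences (same length, ``-`` for
    gaps).  Candidate sites are ungapped columns whose bases differ.
    ``pileups`` maps ``(genome, transcript_position)`` with genome ``"R"``
    or ``"C"`` to per-base read counts from the parental libraries; a
    candidate is kept only if, in each parent with coverage >= ``min_cov``,
    the expected allele's frequency is >= ``min_concordance``.  Without a
    pileup entry a parent contributes no evidence (concordance defaults to
    1.0, i.e. the alignment is trusted).
    """
    if len(aln_r) != len(aln_c):
        raise ValueError("aligned sequences must have equal length")
    snps = []
    pos_r = pos_c = 0
    for br, bc in zip(aln_r.upper(), aln_c.upper()):
        gap_r, gap_c = br == "-", bc == "-"
        if not gap_r and not gap_c and br != bc:
            conc = {}
            ok = True
            for genome, pos, allele in (("R", pos_r, br), ("C", pos_c, bc)):
                conc[genome] = 1.0
                pile = None if pileups is None else pileups.get((genome, pos))
                if pile is not None:
                    cov = sum(pile.values())
                    if cov >= min_cov:
                        conc[genome] = pile.get(allele, 0) / cov
                        if conc[genome] < min_concordance:
                            ok = False
            if ok:
                snps.append(
                    DiagnosticSnp(pair_id, pos_r, pos_c, br, bc, conc["R"], conc["C"])
                )
        if not gap_r:
            pos_r += 1
        if not gap_c:
            pos_c += 1
    return snps


def write_snp_table(snps: Iterable[DiagnosticSnp], path: str | Path) -> None:
    """Tab-delimited SNP table with 1-based transcript positions."""
    df = pd.DataFrame(
        [
            {
                "pair_id": s.pair_id,
                "pos_r": s.pos_r + 1,
                "pos_c": s.pos_c + 1,
                "allele_r": s.allele_r,
                "allele_c": s.allele_c,
                "concordance_r": s.concordance_r,
                "concordance_c": s.concordance_c,
            }
            for s in snps
        ],
        columns=[
            "pair_id", "pos_r", "pos_c", "allele_r", "allele_c",
            "concordance_r", "concordance_c",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> list[DiagnosticSnp]:
    df = pd.read_csv(path, sep="\t")
    return [
        DiagnosticSnp(
            str(r.pair_id), int(r.pos_r) - 1, int(r.pos_c) - 1,
            str(r.allele_r), str(r.allele_c),
            float(getattr(r, "concordance_r", 1.0)),
            float(getattr(r, "concordance_c", 1.0)),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# read binning
# ---------------------------------------------------------------------------

def bin_reads(
    sam_path: str | Path,
    snps: Sequence[DiagnosticSnp],
    sample_id: str,
    library_size: int | None = None,
    return_assignments: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each aligned read to the R or C homoeologue bin by its alleles.

    Alignments are read from a SAM/BAM file whose references are the R
    transcripts.  For every diagnostic site a read overlaps, the read votes
    R if it carries the R allele and C if it carries the C allele; the read
    goes to the majority-vote bin, or to ``ambiguous`` on a tie, when it
    overlaps no informative site, or when an indel/clip interrupts any
    overlapped site.  Reads mapped to references without diagnostic SNPs
    (or unknown references) are counted as ambiguous for that pair, or
    under the pseudo-pair ``__unpaired__`` when the reference is unknown.

    Returns one row per orthologue pair with columns
    ``pair_id, sample, r_count, c_count, ambiguous, r_per_million,
    c_per_million``.  Per-million values are normalised against
    ``library_size`` (defaults to the number of mapped reads in the file).
    With ``return_assignments`` a second DataFrame lists each read's
    individual bin (``read, pair_id, bin``).
    """
    assignments: list[tuple[str, str, str]] = []
    by_ref: dict[str, list[DiagnosticSnp]] = {}
    for s in snps:
        by_ref.setdefault(s.pair_id, []).append(s)
    counts: dict[str, np.ndarray] = {
        p: np.zeros(3, dtype=np.int64) for p in by_ref
    }
    counts["__unpaired__"] = np.zeros(3, dtype=np.int64)
    n_mapped = 0
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            n_mapped += 1
            ref = read.reference_name
            if ref not in by_ref:
                counts["__unpaired__"][2] += 1
                continue
            site_pos = {s.pos_r: s for s in by_ref[ref]}
            votes_r = votes_c = 0
            broken = False
            # map ref pos -> query pos for overlapped diagnostic sites
            ref_to_query = {
                rpos: qpos
                for qpos, rpos in read.get_aligned_pairs(matches_only=False)
                if rpos is not None
            }
            start, end = read.reference_start, read.reference_end
            seq = read.query_sequence or ""
            for pos, snp in site_pos.items():
                if pos < start or pos >= end:
                    continue
                qpos = ref_to_query.get(pos)
                if qpos is None:  # deletion over the site
                    broken = True
                    break
                base = seq[qpos].upper() if qpos < len(seq) else "N"
                if base == snp.allele_r:
                    votes_r += 1
                elif base == snp.allele_c:
                    votes_c += 1
            if broken or votes_r == votes_c:
                counts[ref][2] += 1
                bin_label = "ambiguous"
            elif votes_r > votes_c:
                counts[ref][0] += 1
                bin_label = "R"
            else:
                counts[ref][1] += 1
                bin_label = "C"
            if return_assignments:
                assignments.append((read.query_name, ref, bin_label))
    if library_size is None:
        library_size = n_mapped
    rows = []
    for pair_id in sorted(counts):
        r, c, amb = counts[pair_id]
        rows.append(
            {
                "pair_id": pair_id,
                "sample": sample_id,
                "r_count": int(r),
                "c_count": int(c),
                "ambiguous": int(amb),
                "r_per_million": 1e6 * r / library_size if library_size else np.nan,
                "c_per_million": 1e6 * c / library_size if library_size else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if return_assignments:
        return table, pd.DataFrame(assignments, columns=["read", "pair_id", "bin"])
    return table


# ---------------------------------------------------------------------------
# silencing / novel expression
# ---------------------------------------------------------------------------

def call_expression_status(
    hybrid_counts: pd.DataFrame,
    parental_per_million: pd.DataFrame,
    threshold_per_million: float = SILENCE_THRESHOLD_PER_MILLION,
) -> pd.DataFrame:
    """Silencing and novel-expression flags per orthologue pair in one hybrid.

    ``hybrid_counts`` is an aggregated homoeologue count table for one
    hybrid (columns ``pair_id, r_per_million, c_per_million``).
    ``parental_per_million`` gives each pair's whole-gene reads-per-million
    in the two parents (columns ``R`` and ``C``, indexed by pair id).

    A homoeologue is *silent* below ``threshold_per_million``.  R-silencing:
    the R homoeologue is silent in the hybrid while parent R expressed the
    gene; C-silencing symmetric.  Novel expression: the gene is expressed
    in the hybrid (either homoeologue) while silent in both parents.
    Pairs without parental status are skipped.
    """
    rows = []
    for rec in hybrid_counts.itertuples(index=False):
        pid = rec.pair_id
        if pid.startswith("__") or pid not in parental_per_million.index:
            continue
        pr = float(parental_per_million.at[pid, "R"])
        pc = float(parental_per_million.at[pid, "C"])
        hr, hc = float(rec.r_per_million), float(rec.c_per_million)
        r_expr, c_expr = hr >= threshold_per_million, hc >= threshold_per_million
        pr_expr, pc_expr = pr >= threshold_per_million, pc >= threshold_per_million
        novel = (r_expr or c_expr) and not pr_expr and not pc_expr
        r_sil = (not r_expr) and pr_expr and not novel
        c_sil = (not c_expr) and pc_expr and not novel
        rows.append(
            {
                "pair_id": pid,
                "r_status": "expressed" if r_expr else "silent",
                "c_status": "expressed" if c_expr else "silent",
                "parent_r_status": "expressed" if pr_expr else "silent",
                "parent_c_status": "expressed" if pc_expr else "silent",
                "novel_expression": novel,
                "r_silencing": r_sil,
                "c_silencing": c_sil,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "r_status", "c_status", "parent_r_status",
            "parent_c_status", "novel_expression", "r_silencing", "c_silencing",
        ],
    )


# ---------------------------------------------------------------------------
# HEB states
# ---------------------------------------------------------------------------

def heb_transition(parental_state: str, progeny_state: str) -> str:
    """Transition class from the (parental, progeny) homoeologue-state pair.

    Equal states (including R=C -> R=C) preserve the parental condition;
    a biased parental state collapsing to R=C is loss of bias in the
    progeny; a new or reversed bias is novel bias in the progeny.
    """
    for s in (parental_state, progeny_state):
        if s not in HEB_STATES:
            raise ValueError(f"invalid HEB state {s!r}")
    if parental_state == progeny_state:
        return "parental-condition"
    if progeny_state == "R=C":
        return "no-bias-in-progeny"
    return "novel-bias-in-progeny"


def _parental_state_from_call(call_rc: str) -> str:
    return {"up": "R>C", "ns": "R=C", "down": "R<C"}[call_rc]


def classify_heb(
    parental_call_rc: str,
    r_count: int,
    c_count: int,
    lib_assigned: int | None = None,
    alpha: float = HEB_ALPHA,
) -> dict:
    """HEB record for one orthologue pair in one hybrid.

    Parameters
    ----------
    parental_call_rc
        DE call of R vs C between the parental libraries (direction R
        relative to C), giving the parental state.
    r_count, c_count
        Homoeologue-specific read bins in the hybrid.
    lib_assigned
        Total informatively assigned reads of the hybrid library, used as
        the shared margin of the progeny Fisher test.  Defaults to a margin
        large relative to the bins.
    alpha
        Per-pair significance of the progeny test (P < 0.05; no FDR).

    The progeny state tests the R bin against the C bin against a 1:1
    expectation with a two-sided Fisher's exact test; overall bias requires
    significance, potential bias is the sign of the R/C ratio alone
    (ratio exactly 1 counts as potential C bias: the rule is "> 1").
    """
    parental_state = _parental_state_from_call(parental_call_rc)
    r_count, c_count = int(r_count), int(c_count)
    no_data = r_count == 0 and c_count == 0
    if no_data:
        progeny_state = "R=C"
        p = 1.0
    else:
        if lib_assigned is None:
            lib_assigned = max(1_000_000, 100 * (r_count + c_count))
        p = fisher_de(r_count, c_count, int(lib_assigned), int(lib_assigned))
        if p < alpha and r_count > c_count:
            progeny_state = "R>C"
        elif p < alpha and c_count > r_count:
            progeny_state = "R<C"
        else:
            progeny_state = "R=C"
    if progeny_state == "R>C":
        overall = "R"
    elif progeny_state == "R<C":
        overall = "C"
    else:
        overall = "none"
    potential = "R" if (c_count > 0 and r_count / c_count > 1) else "C"
    if no_data:
        potential = "C"
    return {
        "parental_state": parental_state,
        "progeny_state": progeny_state,
        "transition": heb_transition(parental_state, progeny_state),
        "overall_bias": overall,
        "potential_bias": potential,
        "p": p,
        "no_data": no_data,
    }


def classify_heb_table(
    parental_de: pd.DataFrame,
    hybrid_counts: pd.DataFrame,
    lib_assigned: int | None = None,
    alpha: float = HEB_ALPHA,
) -> pd.DataFrame:
    """Vector version of :func:`classify_heb` over an aggregated bin table.

    ``parental_de`` is the R-vs-C DE table (indexed by gene = pair id);
    ``hybrid_counts`` has one row per pair with ``r_count``/``c_count``.
    If ``lib_assigned`` is omitted, the table's total assigned reads
    (R + C over all pairs) is used as the shared Fisher margin.
    """
    if lib_assigned is None:
        lib_assigned = int(
            hybrid_counts["r_count"].sum() + hybrid_counts["c_count"].sum()
        )
    rows = []
    for rec in hybrid_counts.itertuples(index=False):
        pid = rec.pair_id
        if pid.startswith("__") or pid not in parental_de.index:
            continue
        out = classify_heb(
            parental_de.at[pid, "call"], rec.r_count, rec.c_count,
            lib_assigned=lib_assigned, alpha=alpha,
        )
        out["pair_id"] = pid
        rows.append(out)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("pair_id")
    return df
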