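"""Pipeline orchestration and report tables.

Runs the full chain — replicate prefilter, all pairwise DE contrasts, ELD
categories, homoeologue binning, HEB states, silencing / novel expression
and MPV trajectories — and assembles summary tables in the shape of the
standard homoeologue-expression reports: per-contrast DE summaries,
novel/silencing counts, the 9-row HEB transition table with overall- and
potential-bias rows, and the merger/doubling trajectory partition, all
with explicit denominators.  A self-consistency audit recomputes every
percentage from its own count and denominator and fails the run on any
mismatch beyond rounding.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de_stats import CountMatrix, call_de, filter_expressed
from .eld import classify_eld_table, summarize_eld
from .homoeolog import (
    SILENCE_THRESHOLD_PER_MILLION,
    call_expression_status,
    classify_heb_table,
    read_snp_table,
    bin_reads,
)
from .trajectory import classify_heb_trajectory, classify_trajectory_table

logger = logging.getLogger("hebkit")

__all__ = ["RunConfig", "ReportBundle", "percentage", "run_pipeline", "subset_report"]

HEB_TRANSITION_ROWS = [
    ("R=C", "R=C", "Parental condition"),
    ("R>C", "R>C", "Parental condition"),
    ("R<C", "R<C", "Parental condition"),
    ("R>C", "R=C", "No bias in progeny"),
    ("R<C", "R=C", "No bias in progeny"),
    ("R=C", "R>C", "Novel bias in progeny"),
    ("R=C", "R<C", "Novel bias in progeny"),
    ("R<C", "R>C", "Novel bias in progeny"),
    ("R>C", "R<C", "Novel bias in progeny"),
]

TRAJECTORY_ROWS = [
    ("no-change", "No change"),
    ("doubling", "Change due to genome doubling"),
    ("merger", "Change due to genome merger"),
    ("other", "Other"),
]


def percentage(count: float, denominator: float, decimals: int = 1) -> float:
    """``100 * count / denominator`` rounded half-up to ``decimals``.

    Half-up rounding matches how published count tables print percentages
    (e.g. 0.0752% -> 0.08 at two decimals).
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    value = Decimal(100) * Decimal(str(count)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """File paths and thresholds for one pipeline run."""

    counts: str
    lengths: str
    samples: str
    snps: str | None = None
    homoeolog_counts: str | None = None
    sam_files: Mapping[str, str] | None = None   # sample id -> SAM path
    gene_subsets: Mapping[str, str] | None = None  # name -> path of id list
    outdir: str = "hebkit_out"
    maternal: str = "R"
    paternal: str = "C"
    hybrids: tuple[str, str] = ("F1", "F18")
    fdr: float = 0.05
    log2fc_min: float = 1.0
    threshold_per_million: float = SILENCE_THRESHOLD_PER_MILLION
    heb_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "hybrids" in data:
            data["hybrids"] = tuple(data["hybrids"])
        return cls(**data)

    def config_hash(self) -> str:
        text = repr(sorted(asdict(self).items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def check_files(self) -> None:
        paths = [self.counts, self.lengths, self.samples]
        if self.snps:
            paths.append(self.snps)
        if self.homoeolog_counts:
            paths.append(self.homoeolog_counts)
        if self.sam_files:
            paths.extend(self.sam_files.values())
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


@dataclass
class ReportBundle:
    """Per-gene result tables plus derived summaries for one run."""

    config: RunConfig | None
    de_tables: dict[str, pd.DataFrame]
    eld_records: dict[str, pd.DataFrame]          # per hybrid
    heb_records: dict[str, pd.DataFrame]          # per hybrid
    status_records: dict[str, pd.DataFrame]       # per hybrid
    trajectory_records: pd.DataFrame
    heb_trajectory_records: pd.DataFrame
    n_genes_in: int = 0
    n_genes_filtered: int = 0
    warnings: list[str] = field(default_factory=list)

    # -- summaries ---------------------------------------------------------
    def de_summary(self) -> pd.DataFrame:
        rows = []
        for name, tab in self.de_tables.items():
            n = len(tab)
            n_up = int((tab["call"] == "up").sum())
            n_down = int((tab["call"] == "down").sum())
            rows.append(
                {
                    "contrast": name,
                    "n_genes": n,
                    "n_de": n_up + n_down,
                    "pct_de": percentage(n_up + n_down, n, 2) if n else 0.0,
                    "n_up": n_up,
                    "n_down": n_down,
                }
            )
        return pd.DataFrame(rows).set_index("contrast")

    def eld_summary(self, hybrid: str) -> pd.DataFrame:
        return summarize_eld(self.eld_records[hybrid]).as_frame()

    def status_summary(self) -> pd.DataFrame:
        """Novel-expression / silencing counts per hybrid."""
        rows = []
        for hybrid, tab in self.status_records.items():
            denom = len(tab)
            for label, col in (
                ("novel_expression", "novel_expression"),
                ("r_silencing", "r_silencing"),
                ("c_silencing", "c_silencing"),
            ):
                n = int(tab[col].sum()) if denom else 0
                rows.append(
                    {
                        "hybrid": hybrid,
                        "event": label,
                        "count": n,
                        "denominator": denom,
                        "pct": percentage(n, denom, 2) if denom else 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def heb_summary(self, hybrid: str) -> pd.DataFrame:
        """Transition table with overall- and potential-bias rows."""
        tab = self.heb_records[hybrid]
        denom = len(tab)
        rows = []
        for parental, progeny, label in HEB_TRANSITION_ROWS:
            n = int(
                ((tab["parental_state"] == parental) & (tab["progeny_state"] == progeny)).sum()
            )
            rows.append(
                {
                    "parental": parental,
                    "progeny": progeny,
                    "description": label,
                    "count": n,
                    "pct": percentage(n, denom, 1) if denom else 0.0,
                }
            )
        for bias_col, value, label in (
            ("overall_bias", "R", "Overall R-biased in progeny"),
            ("overall_bias", "C", "Overall C-biased in progeny"),
            ("potential_bias", "R", "Potential R-biased in progeny"),
            ("potential_bias", "C", "Potential C-biased in progeny"),
        ):
            n = int((tab[bias_col] == value).sum()) if denom else 0
            rows.append(
                {
                    "parental": "",
                    "progeny": "",
                    "description": label,
                    "count": n,
                    "pct": percentage(n, denom, 1) if denom else 0.0,
                }
            )
        out = pd.DataFrame(rows)
        out.attrs["denominator"] = denom
        return out

    def trajectory_summary(self, which: str = "global") -> pd.DataFrame:
        tab = (
            self.trajectory_records
            if which == "global"
            else self.heb_trajectory_records
        )
        col = "trajectory"
        denom = len(tab)
        rows = []
        for cls, label in TRAJECTORY_ROWS:
            n = int((tab[col] == cls).sum()) if denom else 0
            rows.append(
                {
                    "class": cls,
                    "description": label,
                    "count": n,
                    "pct": percentage(n, denom, 1) if denom else 0.0,
                }
            )
        out = pd.DataFrame(rows)
        out.attrs["denominator"] = denom
        return out

    # -- integrity ---------------------------------------------------------
    def audit(self) -> None:
        """Recompute every summary percentage from its own counts.

        Raises ``AssertionError`` on any mismatch beyond rounding and
        checks that summary rows sum to their stated denominators.
        """
        for hybrid in self.heb_records:
            heb = self.heb_summary(hybrid)
            denom = heb.attrs["denominator"]
            trans = heb[heb["parental"] != ""]
            if denom:
                assert int(trans["count"].sum()) == denom, "HEB rows do not sum"
                for rec in heb.itertuples(index=False):
                    assert rec.pct == percentage(rec.count, denom, 1)
        for which in ("global", "heb"):
            tr = self.trajectory_summary(which)
            denom = tr.attrs["denominator"]
            if denom:
                assert int(tr["count"].sum()) == denom, "trajectory rows do not sum"
                for rec in tr.itertuples(index=False):
                    assert rec.pct == percentage(rec.count, denom, 1)
        st = self.status_summary()
        for rec in st.itertuples(index=False):
            if rec.denominator:
                assert rec.pct == percentage(rec.count, rec.denominator, 2)

    # -- output ------------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = ""
        if self.config is not None:
            stamp = (
                f"# hebkit {__version__} seed={self.config.seed} "
                f"config={self.config.config_hash()}\n"
            )

        def _write(df: pd.DataFrame, name: str, index: bool = True) -> None:
            path = outdir / name
            with open(path, "w") as fh:
                if stamp:
                    fh.write(stamp)
                df.to_csv(fh, sep="\t", index=index)

        for name, tab in self.de_tables.items():
            _write(tab, f"de_{name}.tsv")
        for hybrid in self.eld_records:
            _write(self.eld_records[hybrid], f"eld_{hybrid}.tsv")
            _write(self.eld_summary(hybrid), f"eld_summary_{hybrid}.tsv")
        for hybrid in self.heb_records:
            _write(self.heb_records[hybrid], f"heb_{hybrid}.tsv")
            _write(self.heb_summary(hybrid), f"heb_summary_{hybrid}.tsv", index=False)
        _write(self.status_summary(), "status_summary.tsv", index=False)
        _write(self.trajectory_records, "trajectory_global.tsv")
        _write(self.heb_trajectory_records, "trajectory_heb.tsv")
        _write(self.trajectory_summary("global"), "trajectory_summary_global.tsv", index=False)
        _write(self.trajectory_summary("heb"), "trajectory_summary_heb.tsv", index=False)
        _write(self.de_summary(), "de_summary.tsv")


def _aggregate_homoeolog(
    table: pd.DataFrame, samples: Sequence[str], lib_total: float
) -> pd.DataFrame:
    sub = table[table["sample"].isin(samples)]
    agg = (
        sub.groupby("pair_id")[["r_count", "c_count", "ambiguous"]].sum().reset_index()
    )
    agg["r_per_million"] = 1e6 * agg["r_count"] / lib_total
    agg["c_per_million"] = 1e6 * agg["c_count"] / lib_total
    return agg


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    Deterministic given fixed inputs; every filtering step logs genes in
    and out.  Any stage failure raises with the stage name attached.
    """
    config.check_files()
    stage = "load"
    try:
        cm = CountMatrix.from_files(config.counts, config.lengths, config.samples)
        groups = [config.maternal, config.paternal, *config.hybrids]
        n_in = len(cm.genes)

        stage = "filter"
        filtered, removed = filter_expressed(cm, groups)
        logger.info(
            "filter_expressed: %d genes in, %d retained, %d removed",
            n_in, len(filtered.genes), removed,
        )
        assert n_in == len(filtered.genes) + removed

        stage = "differential expression"
        mat, pat = config.maternal, config.paternal
        de: dict[str, pd.DataFrame] = {}
        de[f"{mat}_vs_{pat}"] = call_de(
            filtered, pat, mat, alpha=config.fdr, log2fc_min=config.log2fc_min
        )
        for hyb in config.hybrids:
            for parent in (mat, pat):
                de[f"{hyb}_vs_{parent}"] = call_de(
                    filtered, parent, hyb, alpha=config.fdr,
                    log2fc_min=config.log2fc_min,
                )
        de[f"{config.hybrids[1]}_vs_{config.hybrids[0]}"] = call_de(
            filtered, config.hybrids[0], config.hybrids[1],
            alpha=config.fdr, log2fc_min=config.log2fc_min,
        )

        stage = "ELD classification"
        eld_records = {
            hyb: classify_eld_table(
                de[f"{hyb}_vs_{mat}"], de[f"{hyb}_vs_{pat}"], de[f"{mat}_vs_{pat}"]
            )
            for hyb in config.hybrids
        }

        stage = "homoeologue binning"
        warnings_list: list[str] = []
        if config.homoeolog_counts:
            homo = pd.read_csv(config.homoeolog_counts, sep="\t")
        elif config.sam_files and config.snps:
            snps = read_snp_table(config.snps)
            parts = []
            for sample, path in config.sam_files.items():
                lib = int(cm.library_sizes.get(sample, 0)) or None
                parts.append(bin_reads(path, snps, sample, library_size=lib))
            homo = pd.concat(parts, ignore_index=True)
        else:
            homo = pd.DataFrame(
                columns=[
                    "pair_id", "sample", "r_count", "c_count", "ambiguous",
                    "r_per_million", "c_per_million",
                ]
            )
            warnings_list.append("no homoeologue input; HEB stages skipped")
        if config.snps:
            snp_pairs = {s.pair_id for s in read_snp_table(config.snps)}
            homo = homo[homo["pair_id"].isin(snp_pairs)]

        stage = "expression status"
        parental_pm = pd.DataFrame(
            {
                "R": cm.pooled_counts(mat) * 1e6 / cm.pooled_library_size(mat),
                "C": cm.pooled_counts(pat) * 1e6 / cm.pooled_library_size(pat),
            }
        )
        status_records = {}
        heb_records = {}
        hybrid_agg = {}
        for hyb in config.hybrids:
            samples = [s for s in cm.samples if cm.groups[s] == hyb]
            lib_total = float(cm.library_sizes[samples].sum())
            agg = _aggregate_homoeolog(homo, samples, lib_total)
            hybrid_agg[hyb] = agg
            status_records[hyb] = call_expression_status(
                agg, parental_pm, config.threshold_per_million
            )
            stagelocal = f"HEB classification ({hyb})"
            heb_records[hyb] = classify_heb_table(
                de[f"{mat}_vs_{pat}"], agg, alpha=config.heb_alpha
            )
            logger.info("%s: %d pairs classified", stagelocal, len(heb_records[hyb]))

        stage = "trajectory"
        traj = classify_trajectory_table(
            filtered, f1=config.hybrids[0], f18=config.hybrids[1],
            maternal=mat, paternal=pat,
        )
        h0, h1 = config.hybrids
        if len(heb_records[h0]) and len(heb_records[h1]):
            common = heb_records[h0].index.intersection(heb_records[h1].index)
            heb_traj = pd.DataFrame(
                {
                    "divergence": heb_records[h0].loc[common, "parental_state"],
                    "f1_state": heb_records[h0].loc[common, "progeny_state"],
                    "f18_state": heb_records[h1].loc[common, "progeny_state"],
                }
            )
            heb_traj["trajectory"] = [
                classify_heb_trajectory(d, a, b)
                for d, a, b in zip(
                    heb_traj["divergence"], heb_traj["f1_state"], heb_traj["f18_state"]
                )
            ]
        else:
            heb_traj = pd.DataFrame(
                columns=["divergence", "f1_state", "f18_state", "trajectory"]
            )

        bundle = ReportBundle(
            config=config,
            de_tables=de,
            eld_records=eld_records,
            heb_records=heb_records,
            status_records=status_records,
            trajectory_records=traj,
            heb_trajectory_records=heb_traj,
            n_genes_in=n_in,
            n_genes_filtered=len(filtered.genes),
            warnings=warnings_list,
        )
        stage = "audit"
        bundle.audit()
        return bundle
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def subset_report(bundle: ReportBundle, gene_ids: Sequence[str]) -> ReportBundle:
    """The same report restricted to a gene subset (e.g. growth genes).

    Unknown ids are listed in the bundle's warnings and excluded;
    denominators become the subset sizes.
    """
    wanted = pd.Index(dict.fromkeys(gene_ids))
    known: set[str] = set()
    for tab in bundle.de_tables.values():
        known.update(tab.index)
    for tabs in (bundle.heb_records, bundle.status_records):
        for tab in tabs.values():
            if len(tab):
                key = tab.index if tab.index.name == "pair_id" else tab.get("pair_id", [])
                known.update(key)
    unknown = [g for g in wanted if g not in known]
    warnings_list = list(bundle.warnings)
    if unknown:
        warnings_list.append(f"unknown gene ids in subset: {unknown}")

    def _rows(df: pd.DataFrame) -> pd.DataFrame:
        return df.loc[df.index.intersection(wanted)]

    status_subset = {}
    for hyb, tab in bundle.status_records.items():
        status_subset[hyb] = (
            tab[tab["pair_id"].isin(wanted)] if len(tab) else tab
        )
    return ReportBundle(
        config=bundle.config,
        de_tables={k: _rows(v) for k, v in bundle.de_tables.items()},
        eld_records={k: _rows(v) for k, v in bundle.eld_records.items()},
        heb_records={k: _rows(v) if len(v) else v for k, v in bundle.heb_records.items()},
        status_records=status_subset,
        trajectory_records=_rows(bundle.trajectory_records),
        heb_trajectory_records=_rows(bundle.heb_trajectory_records)
        if len(bundle.heb_trajectory_records)
        else bundle.heb_trajectory_records,
        n_genes_in=len(wanted) - len(unknown),
        n_genes_filtered=len(_rows(bundle.trajectory_records)),
        warnings=warnings_list,
    )
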