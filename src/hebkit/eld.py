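"""Twelve-category expression-level-dominance (ELD) classification.

A gene's expression pattern in a hybrid relative to its two parents is
summarised by three pairwise DE calls — hybrid vs maternal parent (R),
hybrid vs paternal parent (C), and R vs C — and binned into twelve Roman-
numeral categories: transgressive down (I, II, III), transgressive up
(IV, V, VI), paternal expression-level dominance (VII, VIII), maternal
expression-level dominance (IX, X) and additive mid-parent expression
(XI, XII).  Call triples where all three contrasts are non-significant are
``conserved``; the remaining triples (e.g. parents differ but the hybrid
matches both) are ``ambiguous``.

Call direction convention: ``call_hr`` / ``call_hc`` are the hybrid
relative to the named parent (``up`` = hybrid higher), ``call_rc`` is R
relative to C (``up`` = R higher).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .de_stats import CountMatrix, call_de

__all__ = [
    "CATEGORIES",
    "DECISION_TABLE",
    "classify_eld",
    "classify_eld_table",
    "eld_from_counts",
    "summarize_eld",
    "EldSummary",
]

_CALLS = ("up", "down", "ns")

#: the twelve Roman-numeral categories in canonical order.
CATEGORIES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")

#: (call_hr, call_hc, call_rc) -> category, for the 13 informative triples.
DECISION_TABLE: dict[tuple[str, str, str], str] = {
    # transgressive down: hybrid below both parents; numeral by parental relation
    ("down", "down", "up"): "I",    # R > C
    ("down", "down", "ns"): "II",   # R = C
    ("down", "down", "down"): "III",  # R < C
    # transgressive up: hybrid above both parents
    ("up", "up", "down"): "IV",     # R < C
    ("up", "up", "ns"): "V",        # R = C
    ("up", "up", "up"): "VI",       # R > C
    # paternal (C) expression-level dominance: hybrid matches C
    ("up", "ns", "down"): "VII",    # expressed at the higher C level
    ("down", "ns", "up"): "VIII",   # expressed at the lower C level
    # maternal (R) expression-level dominance: hybrid matches R
    ("ns", "down", "down"): "IX",   # expressed at the lower R level
    ("ns", "up", "up"): "X",        # expressed at the higher R level
    # additive mid-parent expression
    ("up", "down", "down"): "XI",   # R < C
    ("down", "up", "up"): "XII",    # R > C
    ("ns", "ns", "ns"): "conserved",
}

# Summary set membership, from the categories' implied inequalities.
MATERNAL_ELD = ("IX", "X")
PATERNAL_ELD = ("VII", "VIII")
UP_ELD = ("VII", "X")
DOWN_ELD = ("VIII", "IX")
TRANSGRESSIVE_UP = ("IV", "V", "VI")
TRANSGRESSIVE_DOWN = ("I", "II", "III")
MID_PARENT = ("XI", "XII")
#: categories where the hybrid is above / below the paternal parent C
VS_C_UP = ("IV", "V", "VI", "X", "XII")
VS_C_DOWN = ("I", "II", "III", "IX", "XI")
#: categories where the hybrid is above / below the maternal parent R
VS_R_UP = ("IV", "V", "VI", "VII", "XI")
VS_R_DOWN = ("I", "II", "III", "VIII", "XII")


def classify_eld(call_hr: str, call_hc: str, call_rc: str) -> str:
    """Category for one call triple (see module docstring for directions)."""
    for c in (call_hr, call_hc, call_rc):
        if c not in _CALLS:
            raise ValueError(f"invalid DE call {c!r}; expected up/down/ns")
    return DECISION_TABLE.get((call_hr, call_hc, call_rc), "ambiguous")


def classify_eld_table(
    de_hr: pd.DataFrame, de_hc: pd.DataFrame, de_rc: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene categories from three DE tables sharing a gene index."""
    genes = de_hr.index.intersection(de_hc.index).intersection(de_rc.index)
    rows = {
        g: classify_eld(de_hr.at[g, "call"], de_hc.at[g, "call"], de_rc.at[g, "call"])
        for g in genes
    }
    out = pd.DataFrame(
        {
            "call_hr": de_hr.loc[genes, "call"],
            "call_hc": de_hc.loc[genes, "call"],
            "call_rc": de_rc.loc[genes, "call"],
            "category": pd.Series(rows),
        }
    )
    return out.rename_axis("gene")


def eld_from_counts(
    cm: CountMatrix, hybrid: str, maternal: str = "R", paternal: str = "C"
) -> pd.DataFrame:
    """Run the three contrasts on a count matrix and classify each gene."""
    de_hr = call_de(cm, maternal, hybrid)
    de_hc = call_de(cm, paternal, hybrid)
    de_rc = call_de(cm, paternal, maternal)
    return classify_eld_table(de_hr, de_hc, de_rc)


@dataclass
class EldSummary:
    """Category totals for one hybrid, with both denominators explicit."""

    counts: pd.Series               # per category incl. conserved/ambiguous
    n_total: int                    # all classified genes
    n_informative: int              # excluding conserved and ambiguous

    @property
    def percentages(self) -> pd.Series:
        """Percent of informative (Roman-numeral) genes per category."""
        cats = self.counts.reindex(CATEGORIES, fill_value=0)
        if self.n_informative == 0:
            return cats.astype(float) * 0.0
        return 100.0 * cats / self.n_informative

    def total(self, cats) -> int:
        return int(self.counts.reindex(cats, fill_value=0).sum())

    def as_frame(self) -> pd.DataFrame:
        rows = {
            "maternal_eld": self.total(MATERNAL_ELD),
            "paternal_eld": self.total(PATERNAL_ELD),
            "eld_up": self.total(UP_ELD),
            "eld_down": self.total(DOWN_ELD),
            "transgressive_up": self.total(TRANSGRESSIVE_UP),
            "transgressive_down": self.total(TRANSGRESSIVE_DOWN),
            "mid_parent": self.total(MID_PARENT),
            "vs_C_up": self.total(VS_C_UP),
            "vs_C_down": self.total(VS_C_DOWN),
            "vs_R_up": self.total(VS_R_UP),
            "vs_R_down": self.total(VS_R_DOWN),
            "conserved": self.total(["conserved"]),
            "ambiguous": self.total(["ambiguous"]),
        }
        return pd.DataFrame(
            {"count": pd.Series(rows, dtype=int)}
        ).rename_axis("set")


def summarize_eld(records: pd.DataFrame) -> EldSummary:
    """Summarise a table from :func:`classify_eld_table`."""
    if len(records) == 0:
        counts = pd.Series(0, index=list(CATEGORIES) + ["conserved", "ambiguous"])
        return EldSummary(counts, 0, 0)
    counts = records["category"].value_counts()
    counts = counts.reindex(
        list(CATEGORIES) + ["conserved", "ambiguous"], fill_value=0
    )
    n_total = int(len(records))
    n_informative = int(counts.reindex(CATEGORIES).sum())
    return EldSummary(counts, n_total, n_informative)
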