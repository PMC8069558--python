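"""CDR3-IMGT length summaries by V group x tissue and by incorporated-D count.

Means are rendered at one decimal, rounded half-up; empty cells render as "-".
Clones in which no D gene is recognisable are kept in the tissue summary but
reported separately from the D-count correlation table.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cdr3_decompose import JunctionDecomposition

__all__ = [
    "summarize_by_v_tissue",
    "summarize_by_dcount",
    "render_table",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _frame(decompositions: list[JunctionDecomposition], v_to_group: dict[str, str] | None) -> pd.DataFrame:
    rows = []
    for d in decompositions:
        if not d.productive:
            continue
        group = v_to_group.get(d.v_label, d.v_label) if v_to_group else d.v_label
        rows.append(
            {
                "clone_id": d.clone_id,
                "tissue": d.tissue,
                "v_group": group,
                "d_count": d.d_count,
                "len_aa": d.cdr3_len_aa,
            }
        )
    return pd.DataFrame(rows)


def _summary(group: pd.Series) -> dict:
    return {
        "n_clones": int(group.size),
        "mean_len": round_half_up(float(group.mean())),
        "min_len": int(group.min()),
        "max_len": int(group.max()),
    }


def summarize_by_v_tissue(
    decompositions: list[JunctionDecomposition], v_to_group: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per (tissue, V group) CDR3 length summary with per-tissue and overall
    totals; only productive clones are counted."""
    df = _frame(decompositions, v_to_group)
    if df.empty:
        return pd.DataFrame(columns=["tissue", "v_group", "n_clones", "mean_len", "min_len", "max_len"])
    rows = []
    tissues = sorted(df["tissue"].unique())
    groups = sorted(df["v_group"].unique())
    for tissue in tissues + ["all"]:
        sub_t = df if tissue == "all" else df[df["tissue"] == tissue]
        for group in groups + ["all"]:
            sub = sub_t if group == "all" else sub_t[sub_t["v_group"] == group]
            if sub.empty:
                continue
            rows.append({"tissue": tissue, "v_group": group, **_summary(sub["len_aa"])})
    return pd.DataFrame(rows)


def summarize_by_dcount(
    decompositions: list[JunctionDecomposition], v_to_group: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (V group, d_count >= 1) CDR3 length summary plus totals.

    Returns (table, zero_d_table): clones without any recognisable D are
    excluded from the correlation table and reported separately.
    """
    df = _frame(decompositions, v_to_group)
    if df.empty:
        empty = pd.DataFrame(columns=["v_group", "d_count", "n_clones", "mean_len", "min_len", "max_len"])
        return empty, empty.copy()
    zero = df[df["d_count"] == 0]
    nonzero = df[df["d_count"] > 0]
    rows = []
    groups = sorted(nonzero["v_group"].unique())
    for group in groups + ["all"]:
        sub_g = nonzero if group == "all" else nonzero[nonzero["v_group"] == group]
        for k in sorted(nonzero["d_count"].unique()):
            sub = sub_g[sub_g["d_count"] == k]
            if sub.empty:
                continue
            rows.append({"v_group": group, "d_count": int(k), **_summary(sub["len_aa"])})
    zero_rows = []
    if not zero.empty:
        zero_rows.append({"v_group": "all", "d_count": 0, **_summary(zero["len_aa"])})
    return pd.DataFrame(rows), pd.DataFrame(zero_rows, columns=rows and list(rows[0]) or None)


def render_table(df: pd.DataFrame) -> str:
    """Markdown rendering with means at one decimal and '-' for empty cells."""
    if df.empty:
        return "(empty)"
    shown = df.copy()
    if "mean_len" in shown:
        shown["mean_len"] = shown["mean_len"].map(lambda v: f"{v:.1f}")
        shown["range"] = shown.apply(lambda r: f"{int(r.min_len)}-{int(r.max_len)}", axis=1)
        shown = shown.drop(columns=["min_len", "max_len"])
    shown = shown.fillna("-").astype(str)
    cols = list(shown.columns)
    widths = [max(len(c), *(len(v) for v in shown[c])) for c in cols]
    header = "| " + " | ".join(c.ljust(w) for c, w in zip(cols, widths)) + " |"
    rule = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    body = [
        "| " + " | ".join(str(v).ljust(w) for v, w in zip(row, widths)) + " |"
        for row in shown.itertuples(index=False)
    ]
    return "\n".join([header, rule, *body])
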