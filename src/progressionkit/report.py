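"""Cohort-level bookkeeping summaries.

Every fraction here is recomputed from a per-unit (per-site / per-patient /
per-CpG) table; nothing is stored independently of the tables it summarizes.
Percentages are on the 0-100 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .somatic import RECURRENT_LOCI


def pct(numerator: int, denominator: int) -> float:
    """100 * n/d, NaN when the denominator is zero."""
    return float("nan") if denominator == 0 else 100.0 * numerator / denominator


def summarize_validation(sites: pd.DataFrame) -> dict:
    """Validation bookkeeping from a per-site table with boolean columns
    ``interrogated`` (targeted by the validation assay) and ``validated``
    (confirmed somatic).  ``pct_validated`` is relative to interrogated."""
    n_total = int(len(sites))
    n_interrogated = int(sites["interrogated"].sum())
    n_validated = int((sites["interrogated"] & sites["validated"]).sum())
    return {
        "n_total": n_total,
        "n_interrogated": n_interrogated,
        "pct_interrogated": pct(n_interrogated, n_total),
        "n_validated": n_validated,
        "pct_validated": pct(n_validated, n_interrogated),
    }


def summarize_drift(drift: pd.DataFrame, large_change: float = 0.10) -> dict:
    """Drift summary from a per-site drift table: fraction significant, and
    fraction of significant sites with |allele-frequency change| above
    ``large_change``."""
    n_tested = int(len(drift))
    sig = drift[drift["significant"]]
    n_sig = int(len(sig))
    n_large = int((sig["abs_change"] > large_change).sum())
    return {
        "n_tested": n_tested,
        "n_significant": n_sig,
        "pct_significant": pct(n_sig, n_tested),
        "n_large_change": n_large,
        "pct_large_change_among_significant": pct(n_large, n_sig),
    }


def summarize_categories(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-category patient counts and percentages from evolution calls."""
    n = len(calls)
    counts = calls["category"].value_counts()
    rows = []
    for cat in ("evolving", "expanding", "static", "contracting"):
        c = int(counts.get(cat, 0))
        if c == 0 and cat == "contracting":
            continue
        rows.append({"category": cat, "n_patients": c, "pct_patients": pct(c, n)})
    return pd.DataFrame(rows)


def summarize_cna(
    groups: pd.DataFrame,
    n_patients: int,
    recurrent: tuple[str, ...] = RECURRENT_LOCI,
) -> dict:
    """Fraction of patients carrying >= 1 sCNA group at a recurrent locus.

    ``groups`` is the labeled per-group table (``patient_id``,
    ``locus_label``); ``n_patients`` is the number of patients assayed for
    sCNAs (patients with zero groups have no rows).
    """
    with_recurrent = groups.loc[groups["locus_label"].isin(recurrent), "patient_id"]
    n_with = int(with_recurrent.nunique())
    return {
        "n_patients": int(n_patients),
        "n_groups": int(len(groups)),
        "n_with_recurrent": n_with,
        "pct_with_recurrent": pct(n_with, n_patients),
    }


def summarize_progression(results: pd.DataFrame) -> dict:
    """Direction summary of a per-CpG progression-test table: how many
    significant CpGs, and what fraction of them gained methylation."""
    sig = results[results["significant"]]
    n_sig = int(len(sig))
    n_up = int((sig["direction"] == "up").sum())
    med_up = float(sig.loc[sig["direction"] == "up", "median_paired_delta"].median()) \
        if n_up else float("nan")
    return {
        "n_tested": int((~results["untested"]).sum()) if "untested" in results else int(len(results)),
        "n_significant": n_sig,
        "n_increasing": n_up,
        "pct_increasing": pct(n_up, n_sig),
        "median_increase_among_up": med_up,
    }


def format_report(sections: dict[str, dict | pd.DataFrame]) -> str:
    """Human-readable text report from named summary sections."""
    lines = []
    for title, content in sections.items():
        lines.append(title)
        lines.append("-" * len(title))
        if isinstance(content, pd.DataFrame):
            lines.append(content.to_string(index=False))
        else:
            for k, v in content.items():
                if isinstance(v, float) and not np.isnan(v):
                    lines.append(f"{k}: {v:.1f}" if "pct" in k else f"{k}: {v:.4g}")
                else:
                    lines.append(f"{k}: {v}")
        lines.append("")
    return "\n".join(lines)
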