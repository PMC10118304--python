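"""Codon-position U-content statistics and chi-square tests.

Two tests recur throughout the analysis:

* a goodness-of-fit test of homogeneous U distribution across the three
  codon positions (df = 2; for df = 2 the p-value has the closed form
  exp(-chi2/2), which the test suite uses as an independent oracle);
* a 2x2 test comparing whole-CDS U proportions between two species
  (df = 1, no continuity correction, significance stars at
  0.05 / 0.01 / 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seqio import CdsRecord, codon_position_indices


@dataclass
class PositionCounts:
    """U counts and site counts per codon position (1, 2, 3)."""

    u_counts: tuple[int, int, int]
    site_counts: tuple[int, int, int]

    @property
    def proportions(self) -> tuple[float, float, float]:
        return tuple(u / s for u, s in zip(self.u_counts, self.site_counts))


@dataclass
class TestResult:
    """A chi-square result carrying the table it was computed from."""

    statistic: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    test_name: str
    degenerate: bool = False

    @property
    def stars(self) -> str:
        """Significance stars: * <0.05, ** <0.01, *** <0.001."""
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def u_content_by_position(record: CdsRecord) -> PositionCounts:
    """Per-codon-position U counts over the retained codon span.

    N sites count toward site totals but never toward U counts.
    """
    idx = codon_position_indices(record)
    u_counts = tuple(sum(1 for i in pos if record.seq[i] == "U") for pos in idx)
    site_counts = tuple(len(pos) for pos in idx)
    return PositionCounts(u_counts=u_counts, site_counts=site_counts)


def windowed_u_sd(record: CdsRecord, window: int = 30):
    """SD of U proportions over consecutive non-overlapping windows.

    The sequence is cut into ``len(seq) // window`` consecutive segments
    (trailing remainder dropped, with a warning when windows are lost);
    the U proportion of each segment is computed and the population SD
    returned. Two variants are reported: ``overall`` ignores codon
    structure (the parenthesised SD of the U-content tables) and
    ``by_position`` stratifies each window's proportion by codon position.

    Returns
    -------
    dict with keys ``overall`` (float) and ``by_position`` (3 floats).
    """
    if window < 3:
        raise ValueError(f"window must be >= 3, got {window}")
    seq = record.seq
    n_win = len(seq) // window
    if n_win < 1:
        raise ValueError(
            f"record {record.id!r}: sequence length {len(seq)} shorter than window {window}"
        )
    if n_win * window != len(seq):
        warnings.warn(
            f"record {record.id!r}: trailing {len(seq) - n_win * window} base(s) "
            f"beyond the last {window}-base window ignored",
            stacklevel=2,
        )
    is_u = np.array([c == "U" for c in seq[: n_win * window]], dtype=float)
    per_window = is_u.reshape(n_win, window)
    overall = float(np.std(per_window.mean(axis=1)))  # population SD

    pos_class = np.array(
        [(i - record.frame_offset) % 3 if i >= record.frame_offset else -1
         for i in range(n_win * window)]
    ).reshape(n_win, window)
    by_position = []
    for p in range(3):
        props = []
        for w in range(n_win):
            mask = pos_class[w] == p
            if mask.any():
                props.append(per_window[w][mask].mean())
        by_position.append(float(np.std(props)) if props else float("nan"))
    return {"overall": overall, "by_position": tuple(by_position)}


def homogeneity_test(
    u_counts, site_counts=None, test_name: str = "U homogeneity across codon positions"
) -> TestResult:
    """Chi-square goodness of fit of U counts to per-position site totals.

    Expected U count at position i is total_U * site_counts[i] / sum(sites);
    with equal site totals this reduces to the uniform 1/3 expectation.
    df = 2. A total U count of zero yields the degenerate (0, p=1) result,
    flagged.
    """
    if isinstance(u_counts, PositionCounts):
        site_counts = u_counts.site_counts
        u_counts = u_counts.u_counts
    u = np.asarray(u_counts, dtype=float)
    if site_counts is None:
        sites = np.ones_like(u)
    else:
        sites = np.asarray(site_counts, dtype=float)
    if np.any(sites <= 0):
        raise ValueError("site totals must all be positive")
    total = u.sum()
    if total == 0:
        return TestResult(
            statistic=0.0, df=len(u) - 1, p=1.0,
            observed=u, expected=np.zeros_like(u),
            test_name=test_name, degenerate=True,
        )
    expected = total * sites / sites.sum()
    stat, p = stats.chisquare(u, f_exp=expected)
    return TestResult(
        statistic=float(stat), df=len(u) - 1, p=float(p),
        observed=u, expected=expected, test_name=test_name,
    )


def two_by_two_test(table, test_name: str = "2x2 chi-square") -> TestResult:
    """2x2 chi-square of independence, df = 1, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"degenerate 2x2 table in {test_name!r}: a marginal total is zero")
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(stat), df=int(df), p=float(p),
        observed=table, expected=expected, test_name=test_name,
    )


def species_vs_reference_test(record_a: CdsRecord, record_b: CdsRecord) -> TestResult:
    """2x2 chi-square of whole-CDS U vs non-U counts between two species.

    No continuity correction and no multiple-testing adjustment, matching
    the raw-asterisk reporting convention of the U-content tables. Counts
    are taken over each whole CDS; no alignment is required.
    """
    table = []
    for r in (record_a, record_b):
        n_u = r.seq.count("U")
        table.append([n_u, len(r.seq) - n_u])
    return two_by_two_test(
        table, test_name=f"U proportion: {record_a.id} vs {record_b.id}"
    )


def composition_report(records: list[CdsRecord], reference: CdsRecord | None = None,
                       window: int = 30):
    """Per-record U-content report (machine version of the U-content tables).

    Columns: id, species, gene, per-position proportions, overall U
    proportion, windowed SD, homogeneity chi2/p/stars and (if a reference
    record is given) the 2x2 test against it.
    """
    import pandas as pd

    rows = []
    for r in records:
        counts = u_content_by_position(r)
        hom = homogeneity_test(counts)
        row = {
            "id": r.id,
            "species": r.species,
            "gene": r.gene,
            "u_prop_pos1": counts.proportions[0],
            "u_prop_pos2": counts.proportions[1],
            "u_prop_pos3": counts.proportions[2],
            "u_prop_overall": r.seq.count("U") / len(r.seq),
            "windowed_sd": windowed_u_sd(r, window)["overall"] if len(r.seq) >= window else float("nan"),
            "homogeneity_chi2": hom.statistic,
            "homogeneity_p": hom.p,
            "homogeneity_stars": hom.stars,
        }
        if reference is not None and reference.id != r.id:
            vs = species_vs_reference_test(r, reference)
            row.update(vs_ref_chi2=vs.statistic, vs_ref_p=vs.p, vs_ref_stars=vs.stars)
        rows.append(row)
    return pd.DataFrame(rows)
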