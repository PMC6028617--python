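"""Inner/outer shell partitioning and per-shell composition statistics.

Residues are split at an accessible-surface-area threshold (default 5 Å²)
into a solvent-exposed outer shell and a buried inner shell.  Per-shell
amino-acid compositions are computed per structure (the structure, not the
residue, is the statistical unit), compared across groups of proteins with
the Kruskal-Wallis test and Dunn's post hoc test, and summarised as signed
percent differences against a control group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sasa import ResidueAccessibility
from .structure_io import THREE_TO_ONE

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS_1",
    "ShellPartition",
    "EmptyShellError",
    "classify_shells",
    "composition",
    "composition_table",
    "percent_difference",
    "kruskal_wallis",
    "dunn_posthoc",
    "group_comparison",
]

AMINO_ACIDS_1 = tuple("ACDEFGHIKLMNPQRSTVWY")
_ONE_LETTER = {aa3: aa1 for aa3, aa1 in THREE_TO_ONE.items()}


class EmptyShellError(ValueError):
    """A shell contains no residues; compositions are undefined, not zero."""


@dataclass
class ShellPartition:
    """Total, exclusive split of residues at an ASA threshold.

    ``outer`` holds residues with ASA ≥ threshold (surface exposed),
    ``inner`` the rest (buried core).
    """

    threshold: float
    outer: list[ResidueAccessibility] = field(default_factory=list)
    inner: list[ResidueAccessibility] = field(default_factory=list)

    def shell(self, which: str) -> list[ResidueAccessibility]:
        if which not in ("inner", "outer"):
            raise ValueError("shell must be 'inner' or 'outer'")
        return self.outer if which == "outer" else self.inner


def classify_shells(accessibilities: list[ResidueAccessibility],
                    threshold: float = 5.0) -> ShellPartition:
    """ASA ≥ threshold → outer shell, else inner shell (strict rule)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    partition = ShellPartition(threshold=threshold)
    for acc in accessibilities:
        (partition.outer if acc.total_asa >= threshold
         else partition.inner).append(acc)
    return partition


def composition(residues: list[ResidueAccessibility]) -> pd.Series:
    """Percentage of each of the 20 amino acids among ``residues``.

    UNK residues are excluded from numerator and denominator (logged).
    Raises :class:`EmptyShellError` on an empty shell rather than
    returning a zero vector.
    """
    letters = [_ONE_LETTER.get(r.res_type) for r in residues]
    n_unk = letters.count(None)
    if n_unk:
        logger.info("composition: excluding %d UNK residues", n_unk)
    letters = [aa for aa in letters if aa is not None]
    if not letters:
        raise EmptyShellError("no standard residues in shell")
    counts = pd.Series(letters).value_counts()
    vec = pd.Series(0.0, index=list(AMINO_ACIDS_1))
    vec[counts.index] = counts.values
    return 100.0 * vec / vec.sum()


def composition_table(
    groups: dict[str, dict[str, list[ResidueAccessibility]]],
    shell: str,
    threshold: float = 5.0,
) -> pd.DataFrame:
    """Per-structure composition vectors for one shell.

    ``groups`` maps group label → structure id → residue accessibilities.
    Returns a DataFrame indexed by (group, structure) with one column per
    amino acid; structures whose shell is empty are dropped (missing, not
    zero-filled) with a logged notice.
    """
    rows, index = [], []
    for group, structures in groups.items():
        for struct_id, accs in structures.items():
            part = classify_shells(accs, threshold)
            try:
                rows.append(composition(part.shell(shell)))
            except EmptyShellError:
                logger.warning("%s/%s: empty %s shell; dropped",
                               group, struct_id, shell)
                continue
            index.append((group, struct_id))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["group", "structure"]))


def percent_difference(group_mean: float, control_mean: float) -> float:
    """Signed percent difference vs the control: 100·(g − c)/c.

    Positive values are enrichments, negative depletions (a −72% value is
    reported in prose as a "72% decrease").
    """
    if control_mean == 0:
        raise ValueError("percent difference undefined for zero control mean")
    return 100.0 * (group_mean - control_mean) / control_mean


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    By convention, completely identical observations across all groups
    give H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least two observations")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(*groups: np.ndarray, labels: list[str] | None = None,
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based post hoc z tests for all group pairs.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1)))·(1/n_i + 1/n_j))
    with tie term T = Σ(t³ − t); two-sided normal p-values adjusted by
    ``adjust`` ∈ {none, bonferroni, holm}.
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unsupported adjustment {adjust!r}")
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    labels = labels or [str(i) for i in range(k)]
    sizes = np.array([len(g) for g in groups])
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(flat)
    ranks = stats.rankdata(flat)
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start:start + n].mean())
        start += n
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    variance = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        variance -= tie_term / (12.0 * (n_total - 1))

    records = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        records.append((labels[i], labels[j], z, p))
    frame = pd.DataFrame(records, columns=["group_a", "group_b", "z", "p"])
    if adjust == "none":
        frame["p_adj"] = frame["p"]
    else:
        frame["p_adj"] = multipletests(frame["p"], method=adjust)[1]
    return frame


def group_comparison(table: pd.DataFrame, control: str,
                     adjust: str = "bonferroni",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-residue-type comparison of composition across groups.

    ``table`` is a :func:`composition_table` result (unit = structure).
    Returns ``(tests, differences)``:

    * ``tests`` — one row per (amino acid, group pair): Kruskal-Wallis H
      and p across all groups plus Dunn's pairwise z and adjusted p;
    * ``differences`` — one row per (amino acid, non-control group):
      signed percent difference of the group mean vs the control mean,
      with a direction word matching the reporting convention (a −72%
      entry reads "decrease").
    """
    group_names = list(dict.fromkeys(table.index.get_level_values("group")))
    if control not in group_names:
        raise ValueError(f"control group {control!r} not present")
    test_rows, diff_rows = [], []
    for aa in table.columns:
        samples = [table.loc[g, aa].to_numpy() for g in group_names]
        h, p = kruskal_wallis(*samples)
        dunn = dunn_posthoc(*samples, labels=group_names, adjust=adjust)
        for rec in dunn.itertuples(index=False):
            test_rows.append({
                "residue": aa, "kw_H": h, "kw_p": p,
                "group_a": rec.group_a, "group_b": rec.group_b,
                "dunn_z": rec.z, "dunn_p": rec.p, "dunn_p_adj": rec.p_adj,
            })
        control_mean = table.loc[control, aa].mean()
        for g in group_names:
            if g == control:
                continue
            try:
                pct = percent_difference(table.loc[g, aa].mean(), control_mean)
            except ValueError:
                pct = np.nan
            diff_rows.append({
                "residue": aa, "group": g, "control": control,
                "group_mean": table.loc[g, aa].mean(),
                "control_mean": control_mean,
                "pct_diff": pct,
                "direction": ("increase" if pct > 0 else
                              "decrease" if pct < 0 else "equal")
                if np.isfinite(pct) else "undefined",
            })
    return pd.DataFrame(test_rows), pd.DataFrame(diff_rows)
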