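"""Per-tree / per-block aggregation and Tukey grouping letters.

Each sampled tree is coded ``B{block}C{number}{row}`` (e.g. ``B1C15A``) and
measured on several replicate photographs.  Per-tree means and standard
deviations per canopy parameter are aggregated into block summaries, and
one-way ANOVA with Tukey-Kramer post-hoc comparisons assigns compact
letter displays: groups that share a letter are not significantly
different at the chosen alpha.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = [
    "TREE_CODE_RE",
    "parse_tree_code",
    "summarize_trees",
    "block_summary",
    "tukey_letters",
    "GroupLetters",
]

TREE_CODE_RE = re.compile(r"^B(?P<block>[12])C(?P<tree>\d+)(?P<row>[AB])$")

PARAMETERS = ["lai", "lai_e", "canopy_cover", "crown_cover", "phi", "omega0"]


def parse_tree_code(code: str) -> tuple[int, int, str]:
    """Split ``B1C15A`` into (block, tree number, row letter)."""
    m = TREE_CODE_RE.match(code.strip())
    if not m:
        raise ValueError(f"malformed tree code: {code!r}")
    return int(m.group("block")), int(m.group("tree")), m.group("row")


def summarize_trees(
    records: pd.DataFrame,
    code_column: str = "sample",
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Per-tree mean/SD over replicate images.

    ``records`` holds one row per image with a parseable tree code; rows
    with malformed codes are rejected with a warning.  Returns one row per
    tree with ``<param>_mean`` / ``<param>_sd`` columns, the block number
    and the replicate count.  SD is the sample standard deviation (ddof=1)
    and 0 for single-image trees.
    """
    parameters = parameters or [p for p in PARAMETERS if p in records.columns]
    valid_rows, blocks = [], {}
    for _, row in records.iterrows():
        try:
            block, _, _ = parse_tree_code(str(row[code_column]))
        except ValueError as exc:
            warnings.warn(f"rejected record: {exc}", stacklevel=2)
            continue
        valid_rows.append(row)
        blocks[str(row[code_column])] = block
    if not valid_rows:
        raise ValueError("no valid records")
    df = pd.DataFrame(valid_rows)
    out = []
    for code, grp in df.groupby(code_column, sort=True):
        entry = {"sample": code, "block": blocks[str(code)], "n_images": len(grp)}
        for p in parameters:
            vals = grp[p].astype(float)
            entry[f"{p}_mean"] = vals.mean()
            entry[f"{p}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        out.append(entry)
    return pd.DataFrame(out)


def block_summary(
    tree_summary: pd.DataFrame,
    parameters: list[str] | None = None,
    weighting: str = "tree",
    per_image: pd.DataFrame | None = None,
    code_column: str = "sample",
) -> pd.DataFrame:
    """Block-level mean/SD of the per-tree means.

    With ``weighting='tree'`` (default) each tree counts once — the
    block mean is the unweighted average of the per-tree means.  With
    ``weighting='image'`` the per-image records (``per_image``) are pooled
    so trees with more replicates weigh more.
    """
    parameters = parameters or [
        p for p in PARAMETERS if f"{p}_mean" in tree_summary.columns
    ]
    rows = []
    if weighting == "tree":
        for block, grp in tree_summary.groupby("block", sort=True):
            entry = {"block": block, "n_trees": len(grp)}
            for p in parameters:
                entry[f"{p}_mean"] = grp[f"{p}_mean"].mean()
                entry[f"{p}_sd"] = grp[f"{p}_mean"].std(ddof=1)
            rows.append(entry)
    elif weighting == "image":
        if per_image is None:
            raise ValueError("image weighting needs the per-image records")
        per_image = per_image.copy()
        per_image["block"] = [
            parse_tree_code(str(c))[0] for c in per_image[code_column]
        ]
        for block, grp in per_image.groupby("block", sort=True):
            entry = {"block": block, "n_trees": grp[code_column].nunique()}
            for p in parameters:
                entry[f"{p}_mean"] = grp[p].astype(float).mean()
                entry[f"{p}_sd"] = grp[p].astype(float).std(ddof=1)
            rows.append(entry)
    else:
        raise ValueError("weighting must be 'tree' or 'image'")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey-Kramer compact letter display

@dataclass
class GroupLetters:
    """Compact letter display at significance level alpha."""

    groups: list[str]
    letters: dict[str, str]
    p_anova: float
    alpha: float
    nonsignificant_pairs: set[frozenset]


def _tukey_kramer_pvalues(samples: dict[str, np.ndarray]) -> tuple[dict, float]:
    names = list(samples)
    k = len(names)
    ns = np.array([len(samples[g]) for g in names])
    means = np.array([np.mean(samples[g]) for g in names])
    df_err = int(ns.sum() - k)
    sse = sum(float(np.sum((samples[g] - np.mean(samples[g])) ** 2)) for g in names)
    mse = sse / df_err if df_err > 0 else 0.0
    pvals = {}
    for i in range(k):
        for j in range(i + 1, k):
            if mse == 0:
                p = 0.0 if means[i] != means[j] else 1.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[i] - means[j]) / se
                p = float(studentized_range.sf(q, k, df_err))
            pvals[frozenset((names[i], names[j]))] = p
    return pvals, mse


def _anova_pvalue(samples: dict[str, np.ndarray]) -> float:
    groups = [np.asarray(v, dtype=float) for v in samples.values()]
    if all(np.var(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        return 1.0 if len(set(means)) == 1 else 0.0
    return float(sps.f_oneway(*groups).pvalue)


def _insert_absorb(names: list[str], ns_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Start with one letter column covering all groups; for each significant
    pair sharing a column, split the column into two (each excluding one
    member of the pair), absorb columns contained in others, and finally
    label columns alphabetically in order of first membership.
    """
    columns: list[set[str]] = [set(names)]
    all_pairs = {
        frozenset((a, b)) for i, a in enumerate(names) for b in names[i + 1 :]
    }
    for pair in sorted(all_pairs - ns_pairs, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                for excl in (a, b):
                    new = col - {excl}
                    if new and not any(new <= other for other in columns):
                        columns.append(new)
        # absorb duplicates/subsets
        columns = [
            c for i, c in enumerate(columns)
            if not any(c < o or (c == o and i > j) for j, o in enumerate(columns))
        ]
    # order columns by the first group they contain (input order)
    order = {g: i for i, g in enumerate(names)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_letters(
    samples: dict[str, np.ndarray] | dict[str, list], alpha: float = 0.05
) -> GroupLetters:
    """One-way ANOVA + Tukey-Kramer pairwise tests + compact letter display.

    Requires at least two groups with at least two replicates each.  With
    zero within-group variance everywhere there is no error term to test
    against: every group gets the same letter and a warning is raised.
    """
    samples = {g: np.asarray(v, dtype=float) for g, v in samples.items()}
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in samples.values()):
        raise ValueError("every group needs at least 2 replicates")
    names = list(samples)
    pvals, mse = _tukey_kramer_pvalues(samples)
    if mse == 0:
        warnings.warn(
            "zero within-group variance everywhere: assigning one letter",
            stacklevel=2,
        )
        ns_pairs = set(pvals)
    else:
        ns_pairs = {pair for pair, p in pvals.items() if p >= alpha}
    letters = _insert_absorb(names, ns_pairs)
    return GroupLetters(
        groups=names,
        letters=letters,
        p_anova=_anova_pvalue(samples),
        alpha=alpha,
        nonsignificant_pairs=ns_pairs,
    )
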