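"""Summary-ratio arithmetic over printed group summaries.

Reproduces the headline comparisons a reader would compute from published
group-mean tables: percent difference to the control group, fold ratios
of treated over control, and differential-expression proportions.  Every
report value carries both the unrounded number and a display-rounded one
matching conventional printed precision (integer percent for body-size
comparisons, one decimal for fold ratios, two decimals for DE
proportions).
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml


@dataclass
class GroupSummary:
    """A printed group mean ± SEM with its sample size."""

    label: str
    mean: float
    sem: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class ComparisonReport:
    value: float          # unrounded
    display: float        # rounded to the printed precision
    kind: str             # "percent_difference" | "fold_ratio" | "de_proportion"
    source: str = ""


def percent_difference(treated: GroupSummary, control: GroupSummary, source: str = "") -> ComparisonReport:
    """100 * (treated - control) / control, display-rounded to integer %."""
    if control.mean == 0:
        raise ValueError("control mean must be nonzero")
    value = 100.0 * (treated.mean - control.mean) / control.mean
    return ComparisonReport(value=value, display=round(value), kind="percent_difference", source=source)


def fold_ratio(treated: GroupSummary, control: GroupSummary, source: str = "") -> ComparisonReport:
    """treated / control, display-rounded to one decimal."""
    if treated.mean <= 0 or control.mean <= 0:
        raise ValueError("fold ratio requires positive means")
    value = treated.mean / control.mean
    return ComparisonReport(value=value, display=round(value, 1), kind="fold_ratio", source=source)


def de_proportion(n_significant: int, n_tested: int, source: str = "") -> ComparisonReport:
    """100 * n_significant / n_tested percent, display-rounded to 2 decimals."""
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if not 0 <= n_significant <= n_tested:
        raise ValueError("need 0 <= n_significant <= n_tested")
    value = 100.0 * n_significant / n_tested
    return ComparisonReport(value=value, display=round(value, 2), kind="de_proportion", source=source)


# ----------------------------------------------------------------------
def load_table_fixtures(path: str | None = None) -> dict:
    """Load printed-table group summaries from YAML.

    With no path, loads the transcribed summary statistics shipped with
    the package.
    """
    if path is None:
        from importlib import resources

        ref = resources.files("shufflepower").joinpath("data/printed_tables.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def standard_report(fixtures: dict | None = None) -> list[ComparisonReport]:
    """Compute the standard comparison set from table fixtures.

    Covers the offspring body-weight percent differences, the
    second-generation LH:testosterone and leptin fold ratios, and the
    miRNA DE proportion.
    """
    fx = fixtures if fixtures is not None else load_table_fixtures()

    def gs(entry: dict) -> GroupSummary:
        return GroupSummary(**entry)

    out = []
    for cmp_ in fx["comparisons"]:
        kind = cmp_["kind"]
        if kind == "percent_difference":
            out.append(percent_difference(gs(cmp_["treated"]), gs(cmp_["control"]), cmp_["source"]))
        elif kind == "fold_ratio":
            out.append(fold_ratio(gs(cmp_["treated"]), gs(cmp_["control"]), cmp_["source"]))
        elif kind == "de_proportion":
            out.append(de_proportion(cmp_["n_significant"], cmp_["n_tested"], cmp_["source"]))
        else:
            raise ValueError(f"unknown comparison kind {kind!r}")
    return out
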