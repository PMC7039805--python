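"""Published contingency tables embedded as versioned fixtures.

These are the printed cell counts from the source study's association
tables — any-histocompatible-child counts per classical HLA locus for
RA and SLE versus shared controls, and the mHag tables among mothers
carrying the relevant HLA restriction allele — each tagged with the
printed crude statistics so the statistical layer can be checked
against them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .stats import TwoByTwo


@dataclass(frozen=True)
class FixtureTable:
    """One printed 2×2 table (rows none / 1-or-more, columns case/control)."""

    key: str
    source: str  # which published table
    disease: str  # case group
    exposure: str  # locus or mHag name
    table: TwoByTwo
    printed_or: float | None = None
    printed_ci: tuple[float, float] | None = None
    printed_p: float | None = None
    note: str = ""


def _t(a, b, c, d):
    return TwoByTwo(a=a, b=b, c=c, d=d)


_FIXTURES: tuple[FixtureTable, ...] = (
    # --- Any-histocompatible-child by locus, RA vs controls -------------
    FixtureTable("T2-A", "table2", "RA", "A", _t(104, 683, 34, 230), 1.0, (0.6, 1.5), 1.00),
    FixtureTable("T2-B", "table2", "RA", "B", _t(111, 814, 27, 99), 1.9, (1.2, 3.1), 0.04),
    FixtureTable("T2-C", "table2", "RA", "C", _t(105, 752, 33, 161), 1.4, (0.9, 2.2), 0.77),
    FixtureTable("T2-DPB1", "table2", "RA", "DPB1", _t(63, 555, 75, 358), 1.8, (1.2, 2.6), 0.01),
    FixtureTable("T2-DQA1", "table2", "RA", "DQA1", _t(74, 597, 64, 316), 1.6, (1.1, 2.3), 0.10),
    FixtureTable("T2-DQB1", "table2", "RA", "DQB1", _t(93, 725, 45, 188), 1.8, (1.2, 2.7), 0.03),
    FixtureTable("T2-DRB1", "table2", "RA", "DRB1", _t(103, 765, 35, 148), 1.6, (1.0, 2.4), 0.28),
    # --- Any-histocompatible-child by locus, SLE vs controls ------------
    FixtureTable("T3-A", "table3", "SLE", "A", _t(78, 683, 39, 230), 1.5, (1.0, 2.3), 0.35),
    FixtureTable("T3-B", "table3", "SLE", "B", _t(101, 814, 16, 99), 1.2, (0.7, 2.2), 1.00),
    FixtureTable("T3-C", "table3", "SLE", "C", _t(92, 752, 25, 161), 1.2, (0.7, 1.9), 1.00),
    FixtureTable("T3-DPB1", "table3", "SLE", "DPB1", _t(64, 555, 53, 358), 1.3, (0.9, 1.9), 1.00),
    FixtureTable("T3-DQA1", "table3", "SLE", "DQA1", _t(69, 597, 48, 316), 1.2, (0.8, 1.9), 1.00),
    FixtureTable("T3-DQB1", "table3", "SLE", "DQB1", _t(85, 725, 32, 188), 1.4, (0.9, 2.1), 1.00),
    FixtureTable(
        "T3-DRB1", "table3", "SLE", "DRB1", _t(103, 765, 35, 148), 1.3, (0.8, 2.2), 1.00,
        note="case counts as printed (103+35 exceeds the SLE n of 117; "
        "printed inconsistency in the source table)",
    ),
    # --- Any mHag-compatible child among restriction carriers, SLE ------
    FixtureTable("T6-SLC19A1", "table6", "SLE", "SLC19A1", _t(24, 111, 22, 98), 0.9, (0.5, 1.7), 0.76),
    FixtureTable("T6-LB-WNK1", "table6", "SLE", "LB-WNK1", _t(45, 252, 50, 188), 1.5, (0.9, 2.3), 0.11),
    FixtureTable("T6-HA-3", "table6", "SLE", "HA-3", _t(32, 152, 34, 140), 1.2, (0.7, 2.1), 0.50),
    FixtureTable("T6-ZAPHIR", "table6", "SLE", "ZAPHIR", _t(29, 117, 10, 106), 0.4, (0.2, 0.8), 0.01),
    FixtureTable("T6-HEATR1", "table6", "SLE", "HEATR1", _t(31, 127, 26, 73), 1.5, (0.8, 2.7), 0.22),
    FixtureTable("T6-C19orf48", "table6", "SLE", "C19orf48", _t(44, 245, 51, 195), 1.4, (0.9, 2.3), 0.13),
    # --- Any HLA+mHag combined-compatible child (Fisher's exact), SLE ---
    FixtureTable("T7-SLC19A1", "table7", "SLE", "SLC19A1", _t(44, 189, 2, 20), printed_p=0.39),
    FixtureTable("T7-LB-WNK1", "table7", "SLE", "LB-WNK1", _t(73, 384, 22, 56), printed_p=0.02),
    FixtureTable("T7-HA-3", "table7", "SLE", "HA-3", _t(57, 251, 9, 41), printed_p=1.0),
    FixtureTable("T7-ZAPHIR", "table7", "SLE", "ZAPHIR", _t(39, 202, 0, 21), printed_p=0.05),
    FixtureTable("T7-HEATR1", "table7", "SLE", "HEATR1", _t(51, 189, 6, 11), printed_p=0.22),
    FixtureTable("T7-C19orf48", "table7", "SLE", "C19orf48", _t(75, 366, 20, 74), printed_p=0.37),
)


def paper_fixture_tables() -> dict[str, FixtureTable]:
    """The embedded published tables, keyed by fixture id (e.g. ``T7-ZAPHIR``)."""
    return {f.key: f for f in _FIXTURES}
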