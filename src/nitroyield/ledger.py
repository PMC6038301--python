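"""The yield ledger: from published growth measurements to ATP/NH4+ yields.

Published biomass yields on ammonium come in several raw forms (cells per
mol NH4+, gDW per mol NH4+, a growth-rate/uptake-rate pair, or a directly
measured ATP/NH4+).  This module normalizes each to a Biomass/NH4+ yield in
gDW mol^-1, converts it to a molar ratio (1:N, biomass counted as a
26 g mol^-1 formula unit), multiplies by the ATP/Biomass yield from the
metabolic model to get the realized ATP/NH4+ yield, and compares that
against the theoretical pathway yields.

Display convention (chosen to reproduce the published table): derived values
are shown at 3 significant figures, half-up, and each derived column is
computed from the previously *displayed* column, not from full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .biomass import EnergyCost

FG_TO_G = 1e-15


@dataclass
class LedgerConfig:
    """Constants of the yield pipeline."""

    biomass_mw: float = 26.0        # g per C-mol biomass formula unit
    fg_per_cell_scm1: float = 20.0  # fg dry weight per cell
    protons_per_atp: float = 4.0
    carbon_g_per_cmol: float = 12.0

    def __post_init__(self):
        for name in ("biomass_mw", "fg_per_cell_scm1", "protons_per_atp",
                     "carbon_g_per_cmol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Measurement:
    """One published raw measurement.

    ``kind`` is one of ``cells_per_mol`` (value: cells mol^-1),
    ``gdw_per_mol`` (gDW mol^-1), ``rate_ratio`` (value: growth rate h^-1,
    value2: uptake mmol gDW^-1 h^-1) or ``atp_per_nh4`` (mol mol^-1, with
    the organism's own ATP/Biomass yield in ``atp_per_gdw``).
    """

    strain: str
    kind: str
    value: float
    value2: float | None = None
    fg_per_cell: float | None = None
    atp_per_gdw: float | None = None
    source: str = ""


@dataclass
class LedgerRow:
    """One fully derived row of the yield table."""

    strain: str
    raw: str
    gdw_per_mol: float
    molar_ratio: str
    atp_per_gdw: float
    atp_per_nh4: float
    source: str = ""
    molar_ratio_n: int = field(default=0)


def round_sig(x: float, ndigits: int = 3) -> float:
    """Round to ``ndigits`` significant figures, half-up."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    quant = Decimal(1).scaleb(exponent - ndigits + 1)
    return float(Decimal(repr(x)).quantize(quant, rounding=ROUND_HALF_UP))


def cells_to_gdw(cells_per_mol: float, fg_per_cell: float) -> float:
    """Cell yield (cells per mol NH4+) to dry-weight yield (gDW per mol)."""
    return round_sig(cells_per_mol * fg_per_cell * FG_TO_G, 3)


def protein_to_dw(fg_protein: float, protein_fraction: float) -> float:
    """Per-cell protein mass to per-cell dry weight (fg), given the protein
    content fraction."""
    return round_sig(fg_protein / protein_fraction, 3)


def rate_ratio_to_gdw(mu: float, q: float) -> float:
    """Growth rate (h^-1) over ammonium uptake (mmol gDW^-1 h^-1) to the
    biomass yield in gDW per mol."""
    return round_sig(1000.0 * mu / q, 3)


def gdw_to_molar_ratio(gdw_per_mol: float, biomass_mw: float = 26.0) -> str:
    """Biomass yield as a molar ratio string 1:N, N = nearest integer of
    biomass_mw / yield."""
    if gdw_per_mol <= 0:
        raise ValueError("biomass yield must be > 0 for a molar ratio")
    n = int(Decimal(repr(biomass_mw / gdw_per_mol)).quantize(
        Decimal(1), rounding=ROUND_HALF_UP))
    return f"1:{n}"


def atp_per_nh4(atp_per_gdw: float, gdw_per_mol: float) -> float:
    """Realized ATP/NH4+ yield: ATP/Biomass x Biomass/NH4+."""
    return round_sig(atp_per_gdw * gdw_per_mol, 3)


def h_per_o_to_atp(h_per_o: float, protons_per_atp: float = 4.0) -> float:
    """Convert a measured H+/O ratio to an ATP/NH4+ yield at the given
    synthase stoichiometry."""
    return round_sig(h_per_o / protons_per_atp, 2)


def global_c_fixation(
    nh4_gt_per_yr: float,
    molar_yield: float,
    carbon_g_per_cmol: float = 12.0,
) -> float:
    """Global carbon fixation (Gt C yr^-1) from an oceanic ammonium
    oxidation flux (Gt yr^-1, nitrogen-mass basis) and a molar biomass
    yield (C-mol biomass per mol NH4+)."""
    return nh4_gt_per_yr / 14.0 * molar_yield * carbon_g_per_cmol


def derive_row(
    m: Measurement, cost: EnergyCost, config: LedgerConfig | None = None
) -> LedgerRow:
    """Populate one ledger row from its raw measurement."""
    config = config or LedgerConfig()
    atp_gdw = m.atp_per_gdw if m.atp_per_gdw is not None else round_sig(
        cost.atp_equivalent, 3)
    if m.kind == "cells_per_mol":
        fg = m.fg_per_cell or config.fg_per_cell_scm1
        gdw = cells_to_gdw(m.value, fg)
        raw = f"{m.value:.3g} cells/mol NH4+"
        atp = atp_per_nh4(atp_gdw, gdw)
    elif m.kind == "gdw_per_mol":
        gdw = round_sig(m.value, 3)
        raw = f"{m.value:.3g} gDW/mol NH4+"
        atp = atp_per_nh4(atp_gdw, gdw)
    elif m.kind == "rate_ratio":
        if m.value2 is None:
            raise ValueError("rate_ratio measurement needs value2 (uptake)")
        gdw = rate_ratio_to_gdw(m.value, m.value2)
        raw = f"{m.value:.3g} 1/h / {m.value2:.3g} mmol/gDW/h"
        atp = atp_per_nh4(atp_gdw, gdw)
    elif m.kind == "atp_per_nh4":
        if m.atp_per_gdw is None:
            raise ValueError("direct ATP/NH4+ measurement needs atp_per_gdw")
        atp = round_sig(m.value, 3)
        gdw = round_sig(m.value / m.atp_per_gdw, 3)
        raw = f"{m.value:.3g} ATP/NH4+"
    else:
        raise ValueError(f"unknown measurement kind {m.kind!r}")
    ratio = gdw_to_molar_ratio(gdw, config.biomass_mw)
    return LedgerRow(
        strain=m.strain,
        raw=raw,
        gdw_per_mol=gdw,
        molar_ratio=ratio,
        atp_per_gdw=atp_gdw,
        atp_per_nh4=atp,
        source=m.source,
        molar_ratio_n=int(ratio.split(":")[1]),
    )


def build_ledger(
    measurements: list[Measurement],
    cost: EnergyCost,
    config: LedgerConfig | None = None,
    theoretical: dict[int, float] | None = None,
) -> tuple[list[LedgerRow], dict]:
    """Derive all rows and compare against the theoretical pathway yields.

    Returns the rows plus a comparison block: for each pathway, the ratio of
    its theoretical ATP/NH4+ yield to the mean realized yield over the rows
    (the "order of magnitude of dissipated energy" figure).
    """
    config = config or LedgerConfig()
    rows = [derive_row(m, cost, config) for m in measurements]
    comparison: dict = {}
    if rows:
        mean_est = sum(r.atp_per_nh4 for r in rows) / len(rows)
        comparison["mean_estimated_atp_per_nh4"] = mean_est
        for pid, theo in (theoretical or {}).items():
            comparison[f"pathway{pid}"] = {
                "theoretical": theo,
                "ratio_theoretical_over_estimated": theo / mean_est,
            }
    return rows, comparison


def reference_measurements() -> list[Measurement]:
    """The eight published yield measurements the ledger reproduces."""
    return [
        Measurement("Nitrosopumilus maritimus SCM1", "cells_per_mol",
                    3.49e13, source="Loescher et al. 2012"),
        Measurement("Nitrosopumilus maritimus SCM1", "cells_per_mol",
                    5e13, source="Koenneke et al. 2005"),
        Measurement("Nitrosopumilus maritimus SCM1", "gdw_per_mol",
                    1.3, source="Koenneke et al. 2014"),
        Measurement("Nitrosopumilus maritimus SCM1", "rate_ratio",
                    0.027, value2=26.5, source="Martens-Habbena et al. 2009"),
        Measurement("Strain PS0", "cells_per_mol",
                    5.31e13, source="Qin et al. 2014"),
        Measurement("Strain HCA1", "cells_per_mol",
                    5.50e13, source="Qin et al. 2014"),
        Measurement("Nitrosopumilus piranensis D3C / adriaticus NF5",
                    "cells_per_mol", 6e13, source="Bayer et al. 2016"),
        Measurement("Nitrosomonas europaea ATCC 19718", "atp_per_nh4",
                    0.171, atp_per_gdw=0.238, source="Poughon et al. 2001"),
    ]
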