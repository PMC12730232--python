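"""Lipid ion libraries: construction, TSV interchange, and the printed-value
consistency checker.

A library is a list of :class:`~simslipid.ions.TheoreticalIon` — every
configured ion form of every species — and is what the annotation engine
searches. ``printed_assignments`` carries the ~70 literature ion assignments
(name, reported m/z, polarity) used as the reference surface for the mass
calculus; ``consistency_report`` recomputes each one and reports the signed
ppm deviation, flagging the two known ~1 Da outliers ([LPC 16:0+K]+ reported
535.3, [PE 20:0+Na]+ reported 547.32) as exceptions rather than failures.
"""

from __future__ import annotations

import pandas as pd

from .formula import Formula, Label
from .ions import IonSpec, TheoreticalIon, annotate, ppm_error
from .species import LipidSpecies, formula_of, parse_shorthand

#: Default ion forms searched per polarity.
POSITIVE_ION_FORMS = (
    IonSpec("+H"),
    IonSpec("+H", water_loss=True),
    IonSpec("+Na"),
    IonSpec("+K"),
)
NEGATIVE_ION_FORMS = (IonSpec("-H"),)


def ion_forms_for(polarity: int):
    return POSITIVE_ION_FORMS if polarity > 0 else NEGATIVE_ION_FORMS


def build_library(species_list, polarity=None, ion_forms=None):
    """All configured ion forms of each species as TheoreticalIon entries."""
    ions = []
    for sp in species_list:
        if ion_forms is not None:
            forms = ion_forms
        elif polarity is not None:
            forms = ion_forms_for(polarity)
        else:
            forms = POSITIVE_ION_FORMS + NEGATIVE_ION_FORMS
        for form in forms:
            ions.append(TheoreticalIon.create(sp, form))
    return ions


# -- TSV interchange ---------------------------------------------------------

LIBRARY_COLUMNS = ["name", "class", "n", "d", "extra_O", "ether", "explicit_formula", "label"]


def species_to_frame(species_list) -> pd.DataFrame:
    rows = []
    for sp in species_list:
        rows.append(
            {
                "name": sp.name,
                "class": sp.class_code,
                "n": sp.n_carbons,
                "d": sp.n_double_bonds,
                "extra_O": sp.extra_oxygens,
                "ether": sp.ether_links,
                "explicit_formula": str(sp.explicit_formula) if sp.explicit_formula else "",
                "label": str(sp.label) if sp.label else "",
            }
        )
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def _label_from_str(text: str) -> Label | None:
    if not text:
        return None
    text = text.strip()
    if text.startswith("13C"):
        return Label("c13", int(text[3:] or 1))
    if text.startswith("15N"):
        return Label("n15", int(text[3:] or 1))
    raise ValueError(f"cannot parse label {text!r}")


def frame_to_species(frame: pd.DataFrame):
    out = []
    for _, row in frame.iterrows():
        explicit = row.get("explicit_formula", "")
        out.append(
            LipidSpecies(
                class_code=str(row["class"]),
                n_carbons=int(row["n"]),
                n_double_bonds=int(row["d"]),
                extra_oxygens=int(row.get("extra_O", 0) or 0),
                ether_links=int(row.get("ether", 0) or 0),
                label=_label_from_str(str(row.get("label", "") or "")),
                explicit_formula=Formula.parse(explicit) if isinstance(explicit, str) and explicit else None,
            )
        )
    return out


def read_species_tsv(path):
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return frame_to_species(frame)


def write_library_tsv(species_list, path):
    """Write species plus computed formula and all configured ion m/z."""
    frame = species_to_frame(species_list)
    formulas, mz_cols = [], {f"mz_{form.suffix}": [] for form in POSITIVE_ION_FORMS + NEGATIVE_ION_FORMS}
    for sp in species_list:
        formulas.append(str(formula_of(sp)))
        for form in POSITIVE_ION_FORMS + NEGATIVE_ION_FORMS:
            ion = TheoreticalIon.create(sp, form)
            mz_cols[f"mz_{form.suffix}"].append(round(ion.mz, 4))
    frame["formula"] = formulas
    for col, vals in mz_cols.items():
        frame[col] = vals
    frame.to_csv(path, sep="\t", index=False)
    return frame


def annotation_report(assignments) -> pd.DataFrame:
    """Flatten annotate() output into the standard report table."""
    rows = []
    for a in assignments:
        best = a.best
        rows.append(
            {
                "observed_mz": a.observed_mz,
                "best_name": best.ion.name if best else "",
                "ion_form": best.ion.ion_spec.suffix if best else "",
                "theoretical_mz": best.ion.mz if best else float("nan"),
                "ppm": best.ppm if best else float("nan"),
                "n_candidates": len(a.candidates),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["observed_mz", "best_name", "ion_form", "theoretical_mz", "ppm", "n_candidates"],
    )


# -- literature assignment surface -------------------------------------------

#: (printed name, reported m/z). Explicit-formula entries are expanded below.
_PRINTED: list[tuple[str, float]] = [
    ("[PC 38:2+H]+", 814.63),
    ("[PC 36:2+Na]+", 808.58),
    ("[PC 38:4+Na]+", 832.58),
    ("[PE 20:0+Na]+", 547.32),
    ("[HexCer 32:2;O3+Na]+", 708.5),
    ("[Cer 34:1;O4+H]+", 570.5),
    ("[DG 34:3+H-H2O]+", 573.49),
    ("[PC 32:1+H]+", 732.55),
    ("[MG 20:5+K]+", 415.22),
    ("[15N-PC 32:0+K]+", 773.53),
    ("[15N-PC 32:1+K]+", 771.51),
    ("[15N-PC 34:1+K]+", 799.54),
    ("[13C-PE 34:3+H]+", 715.51),
    ("[13C-PG 34:0+Na]+", 774.53),
    ("[13C-CerPE 32:2;O2+Na]+", 654.46),
    ("[13C-PC 34:1+K]+", 799.54),
    ("[13C-Cer 34:1;O2+K]+", 577.48),
    ("[13C-Cer 38:2;O2+H]+", 593.57),
    ("[PG 22:4+H]+", 575.3),
    ("[13C-PC 30:1+K]+", 743.48),
    ("[PC 16:4+H]+", 502.26),
    ("[HexCer 30:2;O2+K]+", 680.45),
    ("[PC 34:1-TMA+K]+", 739.47),
    ("[PC 34:1+H]+", 760.59),
    ("[13C-Cer 38:1;O+Na]+", 601.57),
    ("[13C-CerPE 40:4;O2+Na]+", 762.56),
    ("[LPC 16:0+K]+", 535.3),
    ("[PS 36:1-87-H]-", 701.51),
    ("[FA 16:0-H]-", 255.23),
    ("[FA 18:0-H]-", 283.26),
    ("[Cer 38:0;O-H]-", 578.59),
    ("[PS 20:0;O-H]-", 582.3),
    ("[PA 24:2;O3-H]-", 579.29),
    ("[SHexCer 42:2;O2-H]-", 888.62),
    ("[PS 40:6-H]-", 834.53),
    ("[13C2-LPE 26:6-H]-", 582.34),
    ("[LPA 20:4-H]-", 457.24),
    ("[LPE 18:3-H]-", 474.26),
    ("[13C2-PE O-38:5-H]-", 752.54),
    ("[PI 38:3-H]-", 887.57),
    ("[PI 38:4-H]-", 885.55),
    ("[13C-FA 18:3;O-H]-", 294.21),
    ("[13C-PS 44:2-H]-", 899.65),
    ("[13C-FA 16:0-H]-", 256.23),
    ("[13C-LPA 16:1-H]-", 408.22),
    ("[13C-PS 44:12-H]-", 879.5),
    ("[PS 44:8-H]-", 886.56),
    ("[13C-LPI O-18:2-H]-", 582.31),
    ("[13C-LPI 18:0-H]-", 600.32),
    ("[13C-FA 18:0-H]-", 284.26),
    ("[13C-PI 38:8-H]-", 878.49),
    ("[13C-PI 38:7-H]-", 880.5),
    ("[13C-PI 38:2-H]-", 890.58),
    ("[13C-PS 44:0-H]-", 903.69),
    ("[FA 16:1-H]-", 253.22),
    ("[FA 18:1-H]-", 281.25),
    ("[PI 38:5-H]-", 883.53),
    ("[13C-FA 18:1-H]-", 282.25),
    ("[13C-PS 44:13-H]-", 877.48),
    ("[13C-PS 44:14-H]-", 875.47),
    ("[13C-FA 20:4-H]-", 304.23),
    ("[FA 20:4-H]-", 303.23),
    ("[LPI O-18:2-H]-", 581.31),
    ("[13C-PI 38:4-H]-", 886.55),
    ("[13C-PS 44:8-H]-", 887.56),
    ("[13C-PS 42:7-H]-", 861.54),
    ("[13C-PS 36:0-H]-", 791.56),
]

#: Reported assignments that deviate ~1 Da from the standard adduct calculus;
#: the source does not explain them, so they are flagged, never "fixed".
KNOWN_EXCEPTIONS = frozenset({"[LPC 16:0+K]+", "[PE 20:0+Na]+"})

# Fragment / sterol ions reported with explicit elemental compositions.
_PC_HEADGROUP = Formula.parse("C5H15NO4P")


def _explicit_entries():
    """(name, reported mz, species, ionspec) for explicit-formula ions."""
    headgroup = LipidSpecies("PC", 5, 0, explicit_formula=_PC_HEADGROUP)
    headgroup_n15 = LipidSpecies(
        "PC", 5, 0, label=Label("n15", 1), explicit_formula=_PC_HEADGROUP
    )
    sterol = LipidSpecies("ST", 28, 4, explicit_formula=Formula.parse("C28H42O6"))
    pi_frag = LipidSpecies(
        "PI", 21, 1, label=Label("c13", 1), explicit_formula=Formula.parse("C21H40O6P")
    )
    cation = IonSpec(adduct=None, polarity=1)
    return [
        ("[C5H15PNO4]+", 184.07, headgroup, cation),
        ("[15N-C5H15PNO4]+", 185.07, headgroup_n15, cation),
        ("[ST 28:4;O6-H]-", 473.29, sterol, IonSpec("-H")),
        ("[13C-C21H40O6P]-", 420.26, pi_frag, IonSpec(adduct=None, polarity=-1)),
    ]


def printed_assignments() -> list[tuple[str, float, TheoreticalIon]]:
    """The literature assignment surface as (name, reported m/z, ion)."""
    out = []
    for name, reported in _PRINTED:
        sp, ionspec = parse_shorthand(name)
        out.append((name, reported, TheoreticalIon.create(sp, ionspec)))
    for name, reported, sp, ionspec in _explicit_entries():
        out.append((name, reported, TheoreticalIon.create(sp, ionspec)))
    return out


def consistency_report(tol_ppm: float = 100.0) -> pd.DataFrame:
    """Recompute every printed assignment and classify the agreement.

    status: ``ok`` (|ppm| <= tol), ``exception`` (a known, documented ~1 Da
    outlier), ``fail`` (anything else outside tolerance).
    """
    rows = []
    for name, reported, ion in printed_assignments():
        ppm = ppm_error(reported, ion.mz)
        if abs(ppm) <= tol_ppm:
            status = "ok"
        elif name in KNOWN_EXCEPTIONS:
            status = "exception"
        else:
            status = "fail"
        rows.append(
            {
                "name": name,
                "reported_mz": reported,
                "computed_mz": round(ion.mz, 4),
                "ppm": round(ppm, 1),
                "polarity": ion.polarity,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
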