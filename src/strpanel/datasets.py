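"""Packaged reference data for the Apennine brown bear (ABB) 13-locus panel.

The ABB population has been monitored non-invasively for two decades by
multiple laboratories; its published per-locus summary statistics (allele
numbers, heterozygosities, identity probabilities, replicate error rates)
and the inter-laboratory allele-size offsets are the standing reference for
panel design in this population.  They ship with the package both to
parameterize the ABB-like synthetic profile and to let the worked analyses
(panel comparison, accumulation curves, selection rule) run on realistic
inputs without access to the restricted genotype database.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd
import yaml

__all__ = [
    "abb_reference_loci",
    "abb_panels",
    "abb_lab_offsets",
    "PROPOSED_PANEL",
    "COMPLETE_PANEL",
]


def _doc() -> dict:
    ref = importlib.resources.files("strpanel").joinpath("data/abb_like.yaml")
    return yaml.safe_load(ref.read_text())


def abb_reference_loci() -> pd.DataFrame:
    """Published per-locus reference values for the ABB panel.

    One row per autosomal locus with columns: locus, origin, multiplex, A,
    Ne, Ho, He, I, hwe, PID, PIDsib, ADO, FA, range_lab2, range_lab3,
    offset (bp to add to Lab2 scores to obtain Lab3 scores; NaN where the
    locus was never scored at Lab2).  Rows are ordered from most to least
    informative locus.
    """
    rows = []
    for entry in _doc()["loci"]:
        pub = entry["published"]
        rows.append(
            {
                "locus": entry["name"],
                "origin": entry["origin"],
                "multiplex": entry["multiplex"],
                "A": entry["n_alleles"],
                "Ne": pub["ne"],
                "Ho": pub["ho"],
                "He": entry["he"],
                "I": pub["shannon_i"],
                "hwe": pub["hwe"],
                "PID": pub["pid"],
                "PIDsib": pub["pidsib"],
                "ADO": entry["ado"],
                "FA": entry["fa"],
                "range_lab2": tuple(entry["range_lab2"])
                if entry.get("range_lab2")
                else None,
                "range_lab3": tuple(entry["range_lab3"]),
                "offset": entry["offset"],
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def abb_panels() -> dict:
    """The named marker subsets compared for ABB monitoring."""
    return {k: list(v) for k, v in _doc()["panels"].items()}


def abb_lab_offsets() -> dict:
    """Per-locus calibration offsets (add to Lab2 scores to get Lab3 scores)."""
    out = {}
    for entry in _doc()["loci"]:
        out[entry["name"]] = entry["offset"]
    return out


COMPLETE_PANEL = "complete13"
PROPOSED_PANEL = "proposed12"
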