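"""Bundled transcriptions of the published evaluation tables.

The package ships machine-readable copies of the printed benchmark
results: confusion matrices and score panels for the compact-model
(SSP_55) and cross-validation (SSP_CV) classifiers on the CB513-derived
test set and the GSW25 blind set, the observed/predicted structure
strings of the two inhibitor case studies, and the main-chain
hydrogen-bond tallies per prediction outcome.  ``recompute_derived``
re-derives every score from the underlying counts and strings with the
package's own scoring code, so the printed numbers can be checked
end-to-end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

from .scoring import (
    ConfusionMatrix3,
    mcc_class,
    q3,
    q_class,
    q_he_error,
    score_chains,
)

__all__ = ["load_printed_tables", "recompute_derived", "DerivedValue"]

_FIXTURE = "printed_tables.json"
_FIXTURE_SHA256 = "83e741ee1982cbaafb61c62b8ee5dc9087005eb7145d29503e63ad397248a147"


def load_printed_tables(verify: bool = True) -> dict:
    """Load the bundled table transcriptions, verifying their checksum."""
    raw = resources.files("fcrnssp.data").joinpath(_FIXTURE).read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise ValueError(
                f"fixture {_FIXTURE} is corrupted: sha256 {digest} != "
                f"expected {_FIXTURE_SHA256}"
            )
    return json.loads(raw)


@dataclass(frozen=True)
class DerivedValue:
    """One quantity recomputed from fixture counts, next to its printed value."""

    name: str
    computed: float
    printed: float
    n: int  # problem size the quantity was computed over

    @property
    def difference(self) -> float:
        return self.computed - self.printed


def recompute_derived(tables: dict | None = None) -> list[DerivedValue]:
    """Recompute every derived figure of the bundled tables.

    Residue-level scores and MCCs come from the confusion matrices via
    :mod:`fcrnssp.scoring`; the inhibitor per-class accuracies from the
    case-study strings; the MM/MH fractions from the hydrogen-bond
    counts.  (SOV values are printed in the tables but are not
    derivable from confusion counts alone, so they are not recomputed.)
    """
    if tables is None:
        tables = load_printed_tables()
    out: list[DerivedValue] = []

    for dataset in ("cb513", "gsw25"):
        block = tables[dataset]
        for model, entry in block["models"].items():
            cm = ConfusionMatrix3(entry["confusion"])
            printed = entry["printed"]
            total = cm.total
            vals = {
                "q3": q3(cm),
                "q_H": q_class(cm, "H"),
                "q_E": q_class(cm, "E"),
                "q_C": q_class(cm, "C"),
                "mcc_H": mcc_class(cm, "H"),
                "mcc_E": mcc_class(cm, "E"),
                "mcc_C": mcc_class(cm, "C"),
            }
            if "q_he_error" in printed:
                vals["q_he_error"] = q_he_error(cm)
            for key, computed in vals.items():
                out.append(
                    DerivedValue(
                        f"{dataset}.{model}.{key}", computed, printed[key], total
                    )
                )

    for which, entry in tables["inhibitors"].items():
        report = score_chains([(entry["observed"], entry["predicted"])])
        out.append(
            DerivedValue(
                f"inhibitors.{which}.q_C",
                report.q_C,
                entry["printed"]["q_C"],
                len(entry["observed"]),
            )
        )

    for cat, entry in tables["hbond_tally"].items():
        mm, mh = entry["mm"], entry["mh"]
        printed = entry["printed"]
        out.append(
            DerivedValue(
                f"hbond.{cat}.frac_mm", 100.0 * mm / (mm + mh),
                printed["frac_mm"], mm + mh,
            )
        )
        out.append(
            DerivedValue(
                f"hbond.{cat}.frac_mh", 100.0 * mh / (mm + mh),
                printed["frac_mh"], mm + mh,
            )
        )
        out.append(
            DerivedValue(
                f"hbond.{cat}.mm_mh", float(mm + mh), printed["mm_mh"], mm + mh
            )
        )
    return out
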