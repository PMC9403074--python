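"""The published coefficient registry: 9 mean models and 9 SD models.

Three printed entries are typographically corrupt and additionally carry a
sanitized variant (the as-printed form is always retained verbatim):

* **Dmin~GA mean** — printed with two linear terms and coefficients that
  make the model negative over the whole gestational range.  The sanitized
  variant is derived from the internal identity Dmin = Dmax/(1 + DD),
  evaluated with the published Dmax~GA and DD~GA mean models and projected
  onto a cubic polynomial on a dense GA grid (max projection error
  < 7e−3 mm, about 2% of the Dmin SD).
* **DD~GA SD** — the printed slope −0.255×10⁻³ per week gives an SD (~0.134)
  three standard deviations away from what the published worked z-score
  example implies (~0.08 at 24 weeks).  The sanitized slope −2.55×10⁻³ is
  the single-decimal-shift correction that reproduces the worked example
  and matches the magnitude of the DD SD models in BPD and FL.
* **DD~BPD SD** — the printed slope −8.040×10⁻³ per mm drives the SD
  negative above BPD ≈ 16 mm, i.e. everywhere in the usable range; the
  sanitized slope −8.040×10⁻⁴ keeps it positive across 42–95 mm.

``published_registry("sanitized")`` (the scoring default) substitutes the
sanitized variants; ``published_registry("as_printed")`` returns every model
exactly as printed, skipping range validation so the corrupt entries remain
inspectable (their pointwise ``predict_sd`` still refuses non-positive SDs).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .models import PolyModel, Predictor, ReferenceChart, Response

#: validated predictor ranges: GA in weeks; BPD and FL in mm over the same
#: gestational window (18–40 weeks)
PREDICTOR_RANGES: dict[Predictor, tuple[float, float]] = {
    "GA": (18.0, 40.0),
    "BPD": (42.0, 95.0),
    "FL": (28.0, 76.0),
}

#: multiple correlation coefficients reported with the published models
#: (mean-model R, SD-model R); kept for documentation, not used in scoring
PUBLISHED_R: dict[tuple[Response, Predictor], tuple[float, float]] = {
    ("Dmax", "GA"): (0.905, 0.357),
    ("Dmin", "GA"): (0.92, 0.383),
    ("DD", "GA"): (0.796, 0.259),
    ("Dmax", "BPD"): (0.911, 0.291),
    ("Dmin", "BPD"): (0.924, 0.37),
    ("DD", "BPD"): (0.799, 0.219),
    ("Dmax", "FL"): (0.917, 0.345),
    ("Dmin", "FL"): (0.929, 0.398),
    ("DD", "FL"): (0.801, 0.249),
}


def _printed(predictor: Predictor, terms, printed_form=None) -> PolyModel:
    return PolyModel(
        predictor=predictor,
        terms=tuple(terms),
        provenance="published_as_printed",
        printed_form=printed_form,
    )


def _sanitized(predictor: Predictor, terms) -> PolyModel:
    return PolyModel(
        predictor=predictor, terms=tuple(terms), provenance="published_sanitized"
    )


_MEAN_AS_PRINTED: dict[tuple[Response, Predictor], PolyModel] = {
    ("Dmax", "GA"): _printed("GA", [(0, -2.99), (1, 0.32), (2, -2.14e-3)]),
    # corrupt: two linear terms as printed; combined here, verbatim retained
    ("Dmin", "GA"): _printed(
        "GA",
        [(1, -2.41 - 0.210), (3, -3.39e-6)],
        printed_form="Y = -2.41*GA-0.210*GA-3.39*GA^3*10^-6",
    ),
    ("DD", "GA"): _printed("GA", [(0, 0.98), (1, -0.03), (3, 4.48e-6)]),
    ("Dmax", "BPD"): _printed("BPD", [(0, -0.30), (1, 6.33e-2), (3, 7.14e-7)]),
    ("Dmin", "BPD"): _printed("BPD", [(0, 0.187), (1, 1.545e-2), (2, 4.283e-4)]),
    ("DD", "BPD"): _printed("BPD", [(0, 0.8), (1, -0.008), (3, 1.11e-7)]),
    ("Dmax", "FL"): _printed("FL", [(0, -0.17), (1, 8.49e-2), (2, 1.01e-5)]),
    ("Dmin", "FL"): _printed("FL", [(0, -0.11), (1, 4.67e-2), (2, 3.89e-4)]),
    ("DD", "FL"): _printed(
        "FL", [(0, 0.374), (1, 0.013), (2, -4.39e-4), (3, 2.99e-6)]
    ),
}

_SD_AS_PRINTED: dict[tuple[Response, Predictor], PolyModel] = {
    ("Dmax", "GA"): _printed("GA", [(0, -0.227), (1, 0.026)]),
    ("Dmin", "GA"): _printed("GA", [(0, -0.301), (1, 0.027)]),
    ("DD", "GA"): _printed("GA", [(0, 0.140), (1, -0.255e-3)]),
    ("Dmax", "BPD"): _printed("BPD", [(0, -0.055), (1, 7.761e-3)]),
    ("Dmin", "BPD"): _printed("BPD", [(0, -0.203), (1, 9.217e-3)]),
    ("DD", "BPD"): _printed("BPD", [(0, 0.131), (1, -8.040e-3)]),
    ("Dmax", "FL"): _printed("FL", [(0, -0.103), (1, 0.011)]),
    ("Dmin", "FL"): _printed("FL", [(0, -0.157), (1, 0.011)]),
    ("DD", "FL"): _printed("FL", [(0, 0.122), (1, -9.870e-4)]),
}


def _dmin_ga_sanitized_mean() -> PolyModel:
    """Cubic projection of Dmax_mean(GA)/(1 + DD_mean(GA)) on [18, 40] weeks."""
    dmax = _MEAN_AS_PRINTED[("Dmax", "GA")]
    dd = _MEAN_AS_PRINTED[("DD", "GA")]
    grid = np.linspace(18.0, 40.0, 2201)
    target = dmax(grid) / (1.0 + dd(grid))
    coefs = np.polynomial.polynomial.polyfit(grid, target, deg=3)
    return _sanitized("GA", [(p, float(c)) for p, c in enumerate(coefs)])


@lru_cache(maxsize=None)
def _sanitized_overrides() -> dict:
    return {
        ("mean", "Dmin", "GA"): _dmin_ga_sanitized_mean(),
        ("sd", "DD", "GA"): _sanitized("GA", [(0, 0.140), (1, -2.55e-3)]),
        ("sd", "DD", "BPD"): _sanitized("BPD", [(0, 0.131), (1, -8.040e-4)]),
    }


@dataclass(frozen=True)
class RegistryEntry:
    """Both variants of one published (response, predictor) model pair."""

    response: Response
    predictor: Predictor
    mean_as_printed: PolyModel
    sd_as_printed: PolyModel
    mean_sanitized: PolyModel | None  # None when the printed form is sound
    sd_sanitized: PolyModel | None

    @property
    def is_corrupt(self) -> bool:
        return self.mean_sanitized is not None or self.sd_sanitized is not None

    def chart(self, variant: str = "sanitized") -> ReferenceChart:
        rng = PREDICTOR_RANGES[self.predictor]
        if variant == "sanitized":
            return ReferenceChart(
                response=self.response,
                mean_model=self.mean_sanitized or self.mean_as_printed,
                sd_model=self.sd_sanitized or self.sd_as_printed,
                predictor_range=rng,
            )
        if variant == "as_printed":
            return ReferenceChart(
                response=self.response,
                mean_model=self.mean_as_printed,
                sd_model=self.sd_as_printed,
                predictor_range=rng,
                validate=False,
            )
        raise ValueError(f"unknown variant {variant!r}")


@lru_cache(maxsize=None)
def registry_entries() -> tuple[RegistryEntry, ...]:
    """All 9 published model pairs with their sanitized variants where needed."""
    overrides = _sanitized_overrides()
    entries = []
    for key, mean in _MEAN_AS_PRINTED.items():
        response, predictor = key
        entries.append(
            RegistryEntry(
                response=response,
                predictor=predictor,
                mean_as_printed=mean,
                sd_as_printed=_SD_AS_PRINTED[key],
                mean_sanitized=overrides.get(("mean",) + key),
                sd_sanitized=overrides.get(("sd",) + key),
            )
        )
    return tuple(entries)


def published_registry(
    variant: str = "sanitized",
) -> dict[tuple[Response, Predictor], ReferenceChart]:
    """Mapping (response, predictor) → ReferenceChart for all 9 published pairs.

    ``variant="sanitized"`` (default, the scoring choice) substitutes
    corrected models for the three corrupt printed entries;
    ``variant="as_printed"`` returns every coefficient exactly as published.
    """
    return {
        (e.response, e.predictor): e.chart(variant) for e in registry_entries()
    }
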