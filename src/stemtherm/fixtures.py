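"""Published stage-curve parameter sets for the four stemborer species.

The shipped table holds the selected model and its estimated parameters
(with standard errors) for each life stage of *Chilo partellus*,
*Busseola fusca*, *Ostrinia nubilalis* and *Sesamia nonagrioides*, as
reported from nonlinear least-squares fits to literature development-time
data. ``load_fixtures`` turns it into ready-to-simulate species models.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import ConfigurationError
from .models import TPCParameterSet, get_model
from .simulate import DEFAULT_CV, SpeciesDevelopmentModel

__all__ = ["SPECIES", "load_parameter_table", "load_fixtures", "species_model"]

SPECIES = (
    "chilo_partellus",
    "busseola_fusca",
    "ostrinia_nubilalis",
    "sesamia_nonagrioides",
)

_FIXTURES = {"table3": "tpc_parameters.csv"}


def load_parameter_table(name: str = "table3") -> pd.DataFrame:
    """The raw parameter table: species, stage, model, parameter, estimate, stderr."""
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    with resources.files("stemtherm.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def load_fixtures(name: str = "table3", cv: float = DEFAULT_CV) -> dict[str, SpeciesDevelopmentModel]:
    """Build one :class:`SpeciesDevelopmentModel` per species from a fixture table.

    ``Topt`` rows are reported values for reference only: for every shipped
    model the optimum is a derived trait, not a free parameter, so they are
    not part of the curve parameter sets.
    """
    table = load_parameter_table(name)
    out: dict[str, SpeciesDevelopmentModel] = {}
    for species, sp_rows in table.groupby("species", sort=False):
        curves: dict[str, TPCParameterSet] = {}
        for stage, rows in sp_rows.groupby("stage", sort=False):
            (model_name,) = rows["model"].unique()
            spec = get_model(model_name)
            values = {
                r.parameter: float(r.estimate)
                for r in rows.itertuples()
                if r.parameter in spec.parameter_names
            }
            curves[stage] = TPCParameterSet(model=spec, values=values)
        out[species] = SpeciesDevelopmentModel(species=species, stage_curves=curves, cv=cv)
    return out


def species_model(species: str, name: str = "table3", cv: float = DEFAULT_CV) -> SpeciesDevelopmentModel:
    """Convenience accessor for a single species' development model."""
    models = load_fixtures(name, cv=cv)
    try:
        return models[species]
    except KeyError:
        raise ConfigurationError(
            f"unknown species {species!r}; available: {sorted(models)}"
        ) from None
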