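"""Shared fixtures: small synthetic designs and reference tables."""

import numpy as np
import pandas as pd
import pytest

from leafprint import FormulaDB, SyntheticSpec, generate_feature_matrix, generate_reference


@pytest.fixture()
def small_spec():
    """A fast 2-class design: 8+8 samples, 60 bins, 2 planted of each kind."""
    return SyntheticSpec(n_per_class=8, n_features=60, n_discriminating=2,
                         trend_archetypes=((0.0, 1.0, 2.0, -1.0),),
                         n_trend_features_per_archetype=2, qc_n=3, seed=42)


@pytest.fixture()
def small_study(small_spec):
    fm, truth, meta = generate_feature_matrix(small_spec)
    return fm, truth, meta


@pytest.fixture(scope="session")
def toy_reference():
    db, edges = generate_reference(n_compounds=30, n_pathways=4,
                                   taxonomy_depth=4, seed=5)
    return db, edges


@pytest.fixture()
def glucose_db():
    """Hand-built two-source reference around a glucose-like formula."""
    rows = [
        {"compound_id": "cpd_glc", "formula": "C6H12O6", "mass": 180.06339,
         "source": "primary",
         "lineage": ["Organic compounds", "Organic oxygen compounds",
                     "Organooxygen compounds", "Carbohydrates"],
         "pathway_ids": ["path00"]},
        {"compound_id": "cpd_fru", "formula": "C6H12O6", "mass": 180.06339,
         "source": "primary",
         "lineage": ["Organic compounds", "Organic oxygen compounds",
                     "Organooxygen compounds", "Carbohydrates"],
         "pathway_ids": ["path00"]},
        {"compound_id": "cpd_caf", "formula": "C8H10N4O2", "mass": 194.08038,
         "source": "primary",
         "lineage": ["Organic compounds", "Organoheterocyclic compounds",
                     "Imidazopyrimidines", "Purines"],
         "pathway_ids": ["path01"]},
        {"compound_id": "cpd_fb", "formula": "C7H6O2", "mass": 122.03678,
         "source": "fallback",
         "lineage": ["Organic compounds", "Benzenoids", "Benzoic acids"],
         "pathway_ids": ["path01"]},
    ]
    return FormulaDB(pd.DataFrame(rows))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
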