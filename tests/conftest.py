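import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pgxtypeb.io import (
    TOXICITY,
    DrugEffect,
    GeneAnnotation,
    GeneAnnotationMap,
    VariantRecord,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


def _rec(rsid, gene, consequence, category, effects_by_drug):
    des = tuple(
        DrugEffect(drug, frozenset(ets)) for drug, ets in effects_by_drug.items()
    )
    return VariantRecord(rsid, gene, consequence, category, des)


@pytest.fixture
def hand_cascade():
    """Six hand-built variants where each filter removes exactly one record.

    v1 synonymous; v2 missense efficacy-only; v3 missense with Toxicity/ADR plus
    Efficacy for the same drug; v4 missense Toxicity/ADR-only in an ADME gene;
    v5 missense Toxicity/ADR-only, non-ADME, in ClinVar (the survivor);
    v6 as v5 but absent from ClinVar.
    """
    variants = [
        _rec("rs1", "G1", "synonymous", 1, {"dA": {TOXICITY}}),
        _rec("rs2", "G2", "missense", 1, {"dB": {"Efficacy"}}),
        _rec("rs3", "G3", "missense", 2, {"dC": {TOXICITY, "Efficacy"}}),
        _rec("rs4", "GADME", "missense", 2, {"dD": {TOXICITY}}),
        _rec("rs5", "G5", "missense", 1, {"dE": {TOXICITY}}),
        _rec("rs6", "G6", "missense", 3, {"dF": {TOXICITY}}),
    ]
    genes = GeneAnnotationMap(
        [
            GeneAnnotation("G1"),
            GeneAnnotation("G2"),
            GeneAnnotation("G3"),
            GeneAnnotation("GADME", is_adme=True),
            GeneAnnotation("G5"),
            GeneAnnotation("G6"),
        ]
    )
    clinvar = {"rs1", "rs2", "rs3", "rs4", "rs5"}
    return variants, genes, clinvar


@pytest.fixture
def rng():
    return np.random.default_rng(0)
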