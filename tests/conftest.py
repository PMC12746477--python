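"""Shared fixtures: one desk-scale registration training run feeds several
test modules (training is the expensive step; the trained model is reused
for registration-quality checks and as the frozen encoder of the strategy
classifier)."""

import numpy as np
import pytest

from mrgart import (
    ClassifierConfig,
    PhantomSpec,
    RegistrationConfig,
    build_classifier,
    generate_case,
    generate_cohort,
    predict,
    split_by_patient,
    train_dlir,
    train_dlsp,
)


@pytest.fixture(scope="session")
def trained_dlir():
    """Registration network trained on ten 64x64x32 synthetic fractions."""
    spec = PhantomSpec(seed=11)
    train_cases = generate_cohort(spec, n_patients=5, fractions_per_patient=2,
                                  ats_fraction_target=0.6)
    config = RegistrationConfig.desk_scale(seed=1, epochs=30)
    model, history = train_dlir(train_cases, config)
    return {"model": model, "history": history, "config": config,
            "train_cases": train_cases}


@pytest.fixture(scope="session")
def heldout_cases():
    """Held-out fractions spanning small to large deformations."""
    spec = PhantomSpec(seed=99)
    return [generate_case(spec, f"T{i:02d}", 0, _target_mean_mm=tm)
            for i, tm in enumerate([2.0, 3.0, 4.0])]


@pytest.fixture(scope="session")
def registered_heldout(trained_dlir, heldout_cases):
    """Displacement fields for the held-out cases (registration + refinement
    run once; several tests consume the same fields)."""
    from mrgart import register

    model = trained_dlir["model"]
    fields = [register(model, c.fixed, c.moving)[0] for c in heldout_cases]
    return fields


@pytest.fixture(scope="session")
def trained_dlsp(trained_dlir):
    """Strategy classifier: frozen encoder from the session registration
    model, head trained on 24 patients, evaluated on 12 held-out patients."""
    cohort = generate_cohort(PhantomSpec(seed=33), n_patients=36,
                             fractions_per_patient=5, ats_fraction_target=0.77)
    train_cases, test_cases = split_by_patient(cohort, n_train_patients=24)
    config = ClassifierConfig.desk_scale(seed=5)
    classifier = build_classifier(trained_dlir["model"], config)
    classifier, bce_history = train_dlsp(classifier, train_cases, config)
    results = [predict(classifier, c) for c in test_cases]
    return {
        "classifier": classifier,
        "bce_history": bce_history,
        "train_cases": train_cases,
        "test_cases": test_cases,
        "labels": np.array([int(c.label) for c in test_cases]),
        "probs": np.array([r.probability for r in results]),
        "results": results,
    }
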