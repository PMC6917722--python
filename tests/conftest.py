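import warnings

import pytest

import lumenfba as lf

TOY_DOSES = [0.0, 0.5, 1.0]


@pytest.fixture(scope="session")
def toy_host():
    return lf.make_toy_host()


@pytest.fixture(scope="session")
def fp_microbe():
    return lf.make_toy_microbe(lf.FP_LIKE)


@pytest.fixture(scope="session")
def bt_microbe():
    return lf.make_toy_microbe(lf.BT_LIKE)


@pytest.fixture(scope="session")
def null_microbe():
    return lf.make_toy_microbe(lf.NULL_SECRETOR)


@pytest.fixture(scope="session")
def western_diet():
    return lf.load_diet_preset("western-toy")


@pytest.fixture(scope="session")
def fructan():
    return lf.load_prebiotic_preset("fructan-toy")


@pytest.fixture(scope="session")
def fp_comodel(western_diet):
    """FP-like co-model under the toy western diet (glucose + peptone)."""
    return lf.apply_diet(lf.make_toy_comodel(profile=lf.FP_LIKE), western_diet)


@pytest.fixture(scope="session")
def bt_comodel(western_diet):
    return lf.apply_diet(lf.make_toy_comodel(profile=lf.BT_LIKE), western_diet)


@pytest.fixture(scope="session")
def cofactor_comodel(western_diet):
    return lf.apply_diet(lf.make_toy_comodel(cofactor=True), western_diet)


def to_cobra(model, tmp_path):
    """Independent-route conversion: serialize to COBRA-JSON and load with
    cobrapy (GLPK backend), giving a solver stack disjoint from scipy."""
    cobra = pytest.importorskip("cobra")
    path = tmp_path / f"{model.id}.json"
    lf.write_model(model, path, "cobra-json")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cobra.io.load_json_model(str(path))
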