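import pytest

from kinwalk.params import ModelParams, KineticsParams
from kinwalk import diffusion as dfn
from kinwalk.stepper import StepTable


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def kinetics():
    return KineticsParams()


@pytest.fixture(scope="session")
def default_solution(params):
    """Zero-load, no-obstacle splitting solution on the production grid."""
    return dfn.solve_splitting(dfn.assemble_problem(params), grid_step=0.125)


@pytest.fixture(scope="session")
def default_solution_coarse(params):
    return dfn.solve_splitting(dfn.assemble_problem(params), grid_step=0.25)


@pytest.fixture(scope="session")
def default_solution_fine(params):
    return dfn.solve_splitting(dfn.assemble_problem(params), grid_step=0.0625)


@pytest.fixture(scope="session")
def step_table(params):
    table = StepTable(params=params, grid_step=0.25)
    table.ensure({})
    return table
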