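import pytest

from platesim import ColumnSpec, FlowSpec, SeparationMethod, Solute, TimeGrid


@pytest.fixture
def case1_method() -> SeparationMethod:
    """C18 column of the worked cases: n=100, tm=3 min, beta=2, F=1 mL/min."""
    return SeparationMethod(
        column=ColumnSpec(n_plates=100, dead_time_min=3.0, phase_ratio=2.0),
        flow=FlowSpec(flow_mL_per_min=1.0),
    )


@pytest.fixture
def solute_a() -> Solute:
    """Solute A: K=3 (0.6/0.2 g/L solubility ratio), C0=1 mg/L."""
    return Solute.from_solubilities("A", 0.6, 0.2, C0=1.0)


@pytest.fixture
def case3_solutes() -> list:
    """Five solutes with K = 1, 3, 5, 7, 9, all at C0=1 mg/L."""
    return [
        Solute(name=label, K=float(k), C0=1.0)
        for label, k in zip("ABCDE", (1, 3, 5, 7, 9))
    ]


@pytest.fixture
def fine_grid() -> TimeGrid:
    """[0, 25] min at 0.01-min spacing: resolves every worked-case peak."""
    return TimeGrid(0.0, 25.0, 2501)
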