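from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")

from concordome.io_tables import GeneUniverse, QuantTable


@pytest.fixture
def small_universe() -> GeneUniverse:
    return GeneUniverse.from_iterable(f"G{i:03d}" for i in range(1, 21))


@pytest.fixture
def small_table(small_universe) -> QuantTable:
    """Values 0, 0.05, 0.5, 5, ... cycling so every copy class is hit."""
    cycle = [0.0, 0.05, 0.5, 5.0, 50.0, 500.0, 5000.0]
    values = {g: cycle[i % len(cycle)] for i, g in enumerate(small_universe)}
    return QuantTable(layer_label="toy", values=values)


@pytest.fixture
def quant_file(tmp_path):
    """Write a gene-level TSV and return its path."""

    def _write(rows: dict[str, float], name: str = "table.tsv", value_col: str = "rpkm"):
        path = tmp_path / name
        lines = [f"gene\t{value_col}"] + [f"{g}\t{v}" for g, v in rows.items()]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
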