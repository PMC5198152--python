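from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from trflp.simulate import simulate_study


def run_cli_chain(outdir: Path, seed: int = 17) -> list[Path]:
    """Run the full CLI pipeline into *outdir*; returns the emitted files."""
    from trflp.cli import main as cli_main
    runner = CliRunner()
    o = str(outdir)
    steps = [
        ["simulate", "--seed", str(seed), "--out", o],
        ["digest", f"{o}/reference.fasta", "--out", f"{o}/refdb_digested.csv"],
        ["profile", f"{o}/peaks.csv", "--enzyme", "HaeIII", "--out", f"{o}/hae.csv"],
        ["profile", f"{o}/peaks.csv", "--enzyme", "MspI", "--out", f"{o}/msp.csv"],
        ["assign", "--haeiii", f"{o}/hae.csv", "--mspi", f"{o}/msp.csv",
         "--ref-db", f"{o}/refdb.csv", "--out", f"{o}/taxa.csv"],
        ["ordinate", f"{o}/hae.csv", "--out-prefix", f"{o}/ord",
         "--process-table", f"{o}/process_parameters.csv", "--nperm", "99",
         "--seed", str(seed)],
        ["correlate", f"{o}/taxa.csv", f"{o}/process_parameters.csv",
         "--out", f"{o}/corr.csv"],
        ["tree", f"{o}/reference.fasta", "--out", f"{o}/tree.nwk",
         "--boot", "50", "--seed", str(seed)],
    ]
    for args in steps:
        result = runner.invoke(cli_main, args, catch_exceptions=False)
        assert result.exit_code == 0, f"{args}: {result.output}"
    return sorted(p for p in outdir.iterdir() if p.is_file())


@pytest.fixture()
def cli_chain():
    return run_cli_chain


@pytest.fixture(scope="session")
def noiseless_study():
    """Full synthetic study without sizing error or noise peaks (seed 11)."""
    return simulate_study(seed=11, sizing_sd=0.0, n_noise_peaks=0)


@pytest.fixture(scope="session")
def noisy_study():
    """Synthetic study at default noise settings (seed 11)."""
    return simulate_study(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
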