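import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from famsurvey.pipeline import SurveyConfig, run_survey
from famsurvey.synthetic import (SyntheticConfig, generate_survey_dataset,
                                 write_survey_dataset)

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def survey_dataset():
    """The bundled synthetic genome with planted ground truth."""
    return generate_survey_dataset(SyntheticConfig(rng_seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def survey_paths(survey_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synthetic")
    return write_survey_dataset(survey_dataset, outdir)


@pytest.fixture(scope="session")
def survey_run(survey_dataset, survey_paths, tmp_path_factory):
    """Full pipeline run on the synthetic fixture at default thresholds."""
    outdir = tmp_path_factory.mktemp("survey_out")
    config = SurveyConfig(
        genome=str(survey_paths["genome"]),
        annotation=str(survey_paths["annotation"]),
        proteome=str(survey_paths["proteome"]),
        queries=str(survey_paths["queries"]),
        outdir=str(outdir),
        seed=FIXTURE_SEED,
        bootstrap_replicates=200,
    )
    report = run_survey(config)
    return {"dataset": survey_dataset, "outdir": outdir, "report": report,
            "config": config}


@pytest.fixture(scope="session")
def survey_tables(survey_run):
    outdir = survey_run["outdir"]
    return {
        "members": pd.read_csv(outdir / "members.tsv", sep="\t"),
        "duplications": pd.read_csv(outdir / "duplications.tsv", sep="\t"),
        "structure": pd.read_csv(outdir / "gene_structure.tsv", sep="\t"),
        "subfamilies": pd.read_csv(outdir / "subfamilies.tsv", sep="\t"),
        "elements": pd.read_csv(outdir / "element_counts.tsv", sep="\t"),
    }
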