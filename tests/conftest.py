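import numpy as np
import pytest

from vocscreen import ScorePanelSpec, gen_scores, load_reference_profile
from vocscreen.triage import scoresets_from_frame


@pytest.fixture(scope="session")
def reference_profile():
    return load_reference_profile()


@pytest.fixture()
def planted_panel():
    """Planted 3-cluster panel: 5 TOP, 10 MIDDLE, 5 WORST, tight poses."""
    spec = ScorePanelSpec(
        n_top=5, n_middle=10, n_worst=5, pose_sd=0.05, seed=7, site_id="COX1"
    )
    scores, truth = gen_scores(spec)
    return scoresets_from_frame(scores), truth.set_index("ligand_id")["true_group"]


def random_score_panel(rng: np.random.Generator, site: str = "S"):
    """A random panel of ligands with Gaussian pose scores for oracle tests."""
    from vocscreen.triage import Role, ScoreSet

    n_ligands = int(rng.integers(4, 9))
    sets = []
    for i in range(n_ligands):
        mean = float(rng.uniform(-10.0, -3.0))
        sd = float(rng.uniform(0.05, 1.5))
        poses = list(rng.normal(mean, sd, size=3))
        sets.append(
            ScoreSet(
                ligand_id=f"L{i:02d}",
                site_id=site,
                role=Role.CANDIDATE,
                pose_scores=poses,
            )
        )
    return sets
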