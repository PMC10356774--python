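import pandas as pd
import pytest

from ehrseq import cohort as co
from ehrseq import synthetic_ehr as se


@pytest.fixture(scope="session")
def sim_small():
    """A 2,000-patient simulated claims table with its category map."""
    cfg = se.SimConfig(n_patients=2000, seed=101, risk_effect=2.0)
    cmap = se.default_category_map(se.make_dx_vocabulary(cfg.n_dx_codes), cfg.n_categories)
    return se.simulate_cohort(cfg, cmap), cmap, cfg


@pytest.fixture(scope="session")
def small_cohort(sim_small):
    """Trajectories (min 2 visits), vocabulary, and the category map."""
    visits, cmap, cfg = sim_small
    trajs = co.build_trajectories(visits, cmap.outcome_codes, cfg.index_year, min_visits=2)
    vocab = co.build_vocabulary(trajs)
    return trajs, vocab, cmap


def make_visit_table(rows):
    """Build a visit table from (pid, date, principal, aux, ecause) tuples."""
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "visit_date": date,
                "principal_dx": dx,
                "aux_dx": aux,
                "ecause": ec,
                "procedures": "",
                "facility_id": "FAC00",
                "age_decade": "3",
                "sex": "F",
                "race": "White",
                "payor": "Private",
            }
            for pid, date, dx, aux, ec in rows
        ]
    )


@pytest.fixture
def toy_trajectory():
    """Three-visit trajectory with known codes and gaps."""
    table = make_visit_table(
        [
            ("P1", "2016-06-01", "A00", "B10;B11", ""),
            ("P1", "2018-03-05", "C20", "B10", "I50"),
            ("P1", "2018-11-02", "A00", "", ""),
        ]
    )
    trajs = co.build_trajectories(table, frozenset({"Z99"}), 2018, min_visits=3)
    assert len(trajs) == 1
    return trajs[0]
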