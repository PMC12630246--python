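import datetime as dt
import itertools
import string

import pytest

from pvsignal.icsr import DrugMention, IcsrReport
from pvsignal.simulate import DEFAULT_SMQ_TERMS, SyntheticConfig


def make_report(
    rid="R1",
    date=dt.date(2015, 6, 1),
    hcp=True,
    sex="F",
    age=60.0,
    outcomes=("hospitalization",),
    drugs=(("B01AE07", "dabigatran etexilate"),),
    reactions=("Acute kidney injury",),
):
    return IcsrReport(
        report_id=rid,
        report_date=date,
        reporter_hcp=hcp,
        sex=sex,
        age_years=age,
        outcomes=frozenset(outcomes),
        drugs=tuple(DrugMention(atc5=a, inn=i) for a, i in drugs),
        reactions=tuple(reactions),
    )


def dilute_catalog(n_drugs=40, weight=0.02):
    """Catalog where any single drug holds a small weight share."""
    codes = [
        f"{letter}{num:02d}{a}{b}{num:02d}"
        for letter, num, (a, b) in zip(
            itertools.cycle("ABCDGHJLMNRSV"),
            itertools.cycle(range(1, 10)),
            itertools.product(string.ascii_uppercase[:8], repeat=2),
        )
    ][:n_drugs]
    return tuple((c, f"drug_{c.lower()}", weight) for c in codes)


def small_config(**overrides):
    defaults = dict(
        n_reports=2000,
        case_fraction=0.15,
        drug_catalog=dilute_catalog(12),
        planted={},
        drugs_per_report_dist={1: 0.8, 2: 0.13, 3: 0.04, 4: 0.02, 5: 0.01},
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def smq_file(tmp_path):
    path = tmp_path / "smq.txt"
    path.write_text(
        "# synthetic renal term list\n" + "".join(f"{t}\n" for t in DEFAULT_SMQ_TERMS),
        encoding="utf-8",
    )
    return path
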