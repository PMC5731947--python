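import numpy as np
import pytest

from ocmi.cohort import SITE_CODES, CohortDataset, PatientRecord


def make_record(patient_id="P1", age=50.0, menopause=0, ascites=0, laterality=0,
                meis=None, sites=()):
    """Record with the named sites positive and all others 0."""
    flags = {c: (1 if c in sites else 0) for c in SITE_CODES}
    return PatientRecord(
        patient_id=patient_id, age=age, menopause=menopause, ascites=ascites,
        laterality=laterality, mei_values=dict(meis or {}), site_flags=flags,
    )


def make_cohort(site_lists, meis=None, ascites=None, laterality=None, menopause=None,
                label="fixture"):
    """Cohort from per-patient site lists and optional columnar MEI arrays.

    ``meis`` maps name -> sequence (None entries become missing values).
    """
    n = len(site_lists)
    meis = meis or {}
    records = []
    for i in range(n):
        mei_values = {
            name: (None if col[i] is None else float(col[i])) for name, col in meis.items()
        }
        records.append(make_record(
            patient_id=f"P{i + 1}",
            ascites=int(ascites[i]) if ascites is not None else 0,
            laterality=int(laterality[i]) if laterality is not None else 0,
            menopause=int(menopause[i]) if menopause is not None else 0,
            meis=mei_values,
            sites=site_lists[i],
        ))
    cohort = CohortDataset(records=records, mei_catalog=list(meis.keys()), label=label)
    cohort.validate()
    return cohort


def cohort_with_counts(counts, rng=None, **kwargs):
    """Cohort whose per-patient site counts equal ``counts`` (sites chosen
    deterministically from the catalog head)."""
    site_lists = [tuple(SITE_CODES[:c]) for c in counts]
    return make_cohort(site_lists, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
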