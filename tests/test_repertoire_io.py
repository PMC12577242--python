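import numpy as np
import pytest

from tcrars.exceptions import (
    EmptyRepertoireError,
    FormatError,
    ParameterError,
    StratificationError,
)
from tcrars.repertoire_io import (
    ClinicalRecord,
    Cohort,
    pool_training_tcrs,
    qc_filter,
    read_clinical,
    read_repertoire,
    select_representative,
    split_cohort,
    write_repertoire,
)

from conftest import make_repertoire


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadRepertoire:
    def test_counts_normalized_to_frequencies(self, tmp_path):
        p = _write(
            tmp_path, "r.tsv",
            "junction_aa\tv_call\tj_call\tduplicate_count\n"
            "CASSF\tTRBV2*01\tTRBJ1-1*01\t30\n"
            "CAFYF\tTRBV9*01\tTRBJ2-2*01\t10\n",
        )
        rep = read_repertoire(p, "airr")
        assert [c.frequency for c in rep.clonotypes] == [0.75, 0.25]
        assert rep.clonotypes[0].junction_aa == "CASSF"

    def test_missing_column_names_the_column(self, tmp_path):
        p = _write(tmp_path, "r.tsv", "v_call\tj_call\tfrequency\nTRBV2\tTRBJ1-1\t1\n")
        with pytest.raises(FormatError, match="junction_aa"):
            read_repertoire(p, "airr")

    def test_simple_dialect(self, tmp_path):
        p = _write(
            tmp_path, "r.tsv",
            "cdr3\tv\tj\tfreq\nCASSF\tTRBV2*01\tTRBJ1-1*01\t0.5\n"
            "CAFYF\tTRBV9*01\tTRBJ2-2*01\t0.3\nCAYTF\tTRBV4-1*01\tTRBJ1-2*01\t0.2\n",
        )
        rep = read_repertoire(p, "simple")
        assert len(rep) == 3

    def test_empty_file(self, tmp_path):
        p = _write(tmp_path, "r.tsv", "")
        with pytest.raises(EmptyRepertoireError):
            read_repertoire(p, "airr")

    @pytest.mark.parametrize("dialect", ["airr", "simple"])
    def test_write_read_round_trip(self, tmp_path, dialect):
        rep = make_repertoire(
            "s1", "case",
            [("CASSF", "TRBV2*01", "TRBJ1-1*01", 0.6), ("CAFYF", "TRBV9*01", "TRBJ2-2*01", 0.4)],
        )
        p = tmp_path / "out.tsv"
        write_repertoire(rep, p, dialect)
        back = read_repertoire(p, dialect, subject_id="s1", label="case")
        assert [c.junction_aa for c in back.clonotypes] == ["CASSF", "CAFYF"]
        assert np.allclose(
            [c.frequency for c in back.clonotypes],
            [c.frequency for c in rep.clonotypes],
        )
        assert [c.v_call for c in back.clonotypes] == [c.v_call for c in rep.clonotypes]


class TestQCFilter:
    def test_removes_noncanonical_and_short(self):
        rep = make_repertoire(
            "s", "case",
            [("CASSLF", "TRBV2*01", "TRBJ1-1*01", 1.0),
             ("CAXSF", "TRBV2*01", "TRBJ1-1*01", 1.0),
             ("CAF", "TRBV2*01", "TRBJ1-1*01", 1.0)],
        )
        out = qc_filter(rep, min_len=4, max_len=30)
        assert [c.junction_aa for c in out.clonotypes] == ["CASSLF"]
        assert out.clonotypes[0].frequency == pytest.approx(1.0)

    def test_clean_repertoire_unchanged(self):
        rep = make_repertoire(
            "s", "case",
            [("CASSLF", "TRBV2*01", "TRBJ1-1*01", 0.5),
             ("CAFYFF", "TRBV9*01", "TRBJ2-2*01", 0.5)],
        )
        out = qc_filter(rep)
        assert [c.junction_aa for c in out.clonotypes] == ["CASSLF", "CAFYFF"]
        assert [c.frequency for c in out.clonotypes] == [0.5, 0.5]

    def test_survivor_renormalized(self):
        rep = make_repertoire(
            "s", "case",
            [("CASSLF", "TRBV2*01", "TRBJ1-1*01", 0.5),
             ("CAX", "TRBV2*01", "TRBJ1-1*01", 0.5)],
        )
        out = qc_filter(rep)
        assert out.clonotypes[0].frequency == pytest.approx(1.0)

    def test_all_removed_raises(self):
        rep = make_repertoire("s", "case", [("CAX", "TRBV2*01", "TRBJ1-1*01", 1.0)])
        with pytest.raises(EmptyRepertoireError):
            qc_filter(rep)


class TestSelectRepresentative:
    def test_top_n_by_frequency(self):
        rep = make_repertoire(
            "s", "case",
            [("CAAAF", "TRBV2*01", "TRBJ1-1*01", 0.5),
             ("CBBBF", "TRBV2*01", "TRBJ1-1*01", 0.3),
             ("CCCCF", "TRBV2*01", "TRBJ1-1*01", 0.2)],
        )
        out = select_representative(rep, 2)
        assert [c.junction_aa for c in out.clonotypes] == ["CAAAF", "CBBBF"]
        assert sum(c.frequency for c in out.clonotypes) == pytest.approx(1.0, abs=1e-9)

    def test_n_larger_than_repertoire(self):
        rep = make_repertoire(
            "s", "case", [(f"CA{aa}SF", "TRBV2*01", "TRBJ1-1*01", 1.0) for aa in "DEGH"]
        )
        assert len(select_representative(rep, 2000)) == 4

    def test_tie_broken_lexicographically(self):
        rep = make_repertoire(
            "s", "case",
            [("CABF", "TRBV2*01", "TRBJ1-1*01", 0.4),
             ("CAAF", "TRBV2*01", "TRBJ1-1*01", 0.4),
             ("CADF", "TRBV2*01", "TRBJ1-1*01", 0.2)],
        )
        out = select_representative(rep, 1)
        assert out.clonotypes[0].junction_aa == "CAAF"

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(3)
        freqs = rng.random(20)
        rep = make_repertoire(
            "s", "case",
            [(f"CA{a}{b}F", "TRBV2*01", "TRBJ1-1*01", f)
             for (a, b), f in zip([(x, y) for x in "DEGHI" for y in "DEGH"], freqs)],
        )
        once = select_representative(rep, 8)
        twice = select_representative(once, 8)
        assert [c.junction_aa for c in once.clonotypes] == [
            c.junction_aa for c in twice.clonotypes
        ]
        kept = {c.junction_aa for c in once.clonotypes}
        orig = {c.junction_aa: c.frequency for c in rep.clonotypes}
        min_kept = min(orig[j] for j in kept)
        max_excl = max((f for j, f in orig.items() if j not in kept), default=0.0)
        assert min_kept >= max_excl

    def test_nonpositive_n_rejected(self):
        rep = make_repertoire("s", "case", [("CAAF", "TRBV2*01", "TRBJ1-1*01", 1.0)])
        with pytest.raises(ParameterError):
            select_representative(rep, 0)


def _cohort(n_case=5, n_control=5):
    reps = []
    for i in range(n_case):
        reps.append(make_repertoire(f"p{i}", "case", [("CAAAF", "TRBV2*01", "TRBJ1-1*01", 1.0)]))
    for i in range(n_control):
        reps.append(make_repertoire(f"h{i}", "control", [("CAAAF", "TRBV2*01", "TRBJ1-1*01", 1.0)]))
    return Cohort(reps)


class TestSplitCohort:
    def test_stratified_four_to_one(self):
        train, val = split_cohort(_cohort(), 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2
        assert sorted(train.labels()).count("case") == 4
        assert sorted(val.labels()).count("case") == 1

    def test_deterministic_given_seed(self):
        a = split_cohort(_cohort(), 0.8, seed=42)
        b = split_cohort(_cohort(), 0.8, seed=42)
        assert a[0].subject_ids() == b[0].subject_ids()
        assert a[1].subject_ids() == b[1].subject_ids()

    def test_subject_disjoint_and_exhaustive(self):
        train, val = split_cohort(_cohort(), 0.8, seed=1)
        tr, va = set(train.subject_ids()), set(val.subject_ids())
        assert tr & va == set()
        assert tr | va == set(_cohort().subject_ids())

    def test_single_label_rejected(self):
        with pytest.raises(StratificationError):
            split_cohort(_cohort(n_control=0), 0.8, seed=0)


class TestPoolTrainingTcrs:
    def test_one_row_per_subject_clonotype(self):
        reps = [
            make_repertoire("p0", "case", [(f"CA{a}SF", "TRBV2*01", "TRBJ1-1*01", 1.0) for a in "DEG"]),
            make_repertoire("h0", "control", [(f"CA{a}SF", "TRBV9*01", "TRBJ1-1*01", 1.0) for a in "HIK"]),
        ]
        pool = pool_training_tcrs(Cohort(reps))
        assert len(pool) == 6
        assert set(pool["label"]) == {0, 1}

    def test_cross_label_duplicates_retained(self):
        reps = [
            make_repertoire("p0", "case", [("CADSF", "TRBV2*01", "TRBJ1-1*01", 1.0)]),
            make_repertoire("h0", "control", [("CADSF", "TRBV2*01", "TRBJ1-1*01", 1.0)]),
        ]
        pool = pool_training_tcrs(Cohort(reps))
        assert len(pool) == 2
        assert sorted(pool["label"]) == [0, 1]

    def test_within_subject_duplicates_collapsed(self):
        rep = make_repertoire(
            "p0", "case",
            [("CADSF", "TRBV2*01", "TRBJ1-1*01", 0.5), ("CADSF", "TRBV2*01", "TRBJ1-1*01", 0.5)],
        )
        rep2 = make_repertoire("h0", "control", [("CAHSF", "TRBV2*01", "TRBJ1-1*01", 1.0)])
        pool = pool_training_tcrs(Cohort([rep, rep2]))
        assert len(pool) == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            pool_training_tcrs(Cohort([]))


class TestReadClinical:
    def test_activity_rule(self, tmp_path):
        p = _write(
            tmp_path, "c.csv",
            "subject_id,sledai,c3,c4,dsdna,damage_count\np0,7,80,20,1,2\np1,4,110,28,0,0\n",
        )
        clin = read_clinical(p)
        assert clin["p0"].is_active is True
        assert clin["p1"].is_active is False

    def test_missing_covariate_stored_absent(self, tmp_path):
        p = _write(tmp_path, "c.csv", "subject_id,sledai,c3\np0,7,80\n")
        rec = read_clinical(p)["p0"]
        assert rec.c4 is None and rec.dsdna_positive is None
        assert rec.c3 == 80.0

    def test_duplicate_subject_rejected(self, tmp_path):
        p = _write(tmp_path, "c.csv", "subject_id,sledai\np0,7\np0,4\n")
        with pytest.raises(FormatError):
            read_clinical(p)


def test_activity_cutoff_is_five():
    assert ClinicalRecord(sledai=5).is_active is True
    assert ClinicalRecord(sledai=4).is_active is False
    assert ClinicalRecord().is_active is None
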