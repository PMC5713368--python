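"""Extension loading: registration, transactionality, the 23-function API."""

import numpy as np
import pytest

from seqdesc.alphabet import FaultPolicy, SequenceRecord, TypeRegistry
from seqdesc.extensions import (
    EXTENSION_API_FUNCTIONS,
    ExtensionError,
    ExtensionHost,
    extension_api,
    load_extension,
)
from seqdesc.modes import configure_mode, run_engine
from seqdesc.properties import PropertyRegistry
from seqdesc.synthetic import random_records


@pytest.fixture
def host():
    seqtypes = TypeRegistry()
    return ExtensionHost(seqtypes=seqtypes, properties=PropertyRegistry(seqtypes))


def write_ext(tmp_path, text, name="ext.py"):
    path = tmp_path / name
    path.write_text(text)
    return path


MYAAC = """
def compute():
    counts = kmer_counts(1)
    emit_vector(counts / counts.sum())

register_mode("myaac", "PROT", alphabet_size("PROT"), compute)
"""


class TestAPISurface:
    def test_exactly_23_documented_functions(self):
        assert len(EXTENSION_API_FUNCTIONS) == 23
        api = extension_api()
        assert set(api) == set(EXTENSION_API_FUNCTIONS)
        assert all(callable(fn) for fn in api.values())

    def test_per_sequence_functions_error_outside_compute(self, host):
        api = extension_api(host)
        with pytest.raises(ExtensionError, match="compute rule"):
            api["current_seq_id"]()
        with pytest.raises(ExtensionError, match="compute rule"):
            api["kmer_counts"](1)


class TestLoading:
    def test_registering_a_mode_grows_catalogue(self, host, tmp_path, rng):
        assert len(host.modes.list_modes()) == 35
        manifest = load_extension(write_ext(tmp_path, MYAAC), host)
        assert manifest.modes == ["myaac"]
        assert len(host.modes.list_modes()) == 36
        # the extension mode computes like the built-in aac
        prot = host.seqtypes.get("PROT")
        records = random_records(prot, 3, rng, (10, 30))
        ext = configure_mode("myaac", prot, registry=host.modes,
                             properties=host.properties, seqtypes=host.seqtypes)
        builtin = configure_mode("aac", prot, registry=host.modes,
                                 properties=host.properties, seqtypes=host.seqtypes)
        for a, b in zip(run_engine(records, prot, [ext]),
                        run_engine(records, prot, [builtin])):
            assert np.array_equal(a.values, b.values)

    def test_syntax_error_registers_nothing(self, host, tmp_path):
        bad = write_ext(tmp_path, "register_mode('m1', 'PROT', 1, lambda: 1)\ndef oops(:\n")
        with pytest.raises(ExtensionError, match="syntax error"):
            load_extension(bad, host)
        assert len(host.modes.list_modes()) == 35

    def test_runtime_error_rolls_back_registrations(self, host, tmp_path):
        text = MYAAC + "\nregister_seqtype('XY', ['X', 'Y'])\nraise RuntimeError('late failure')\n"
        with pytest.raises(ExtensionError, match="late failure"):
            load_extension(write_ext(tmp_path, text), host)
        assert "myaac" not in host.modes
        assert "XY" not in host.seqtypes

    def test_mode_id_collision_fails_load(self, host, tmp_path):
        text = "register_mode('aac', 'PROT', 20, lambda: None)\n"
        with pytest.raises(ExtensionError, match="already registered"):
            load_extension(write_ext(tmp_path, text), host)

    def test_missing_file(self, host, tmp_path):
        with pytest.raises(ExtensionError, match="cannot read"):
            load_extension(tmp_path / "absent.py", host)

    def test_user_seqtype_and_property(self, host, tmp_path, rng):
        text = """
register_seqtype("AB2", ["A", "B"])
register_property("abprop", "AB2", 1, {"A": 1.0, "B": 3.0})

def compute():
    pair = build_pair_tables(["abprop"])
    theta = theta_parallel(1, pair)
    emit_vector(theta)

register_mode("abmode", "AB2", 1, compute)
"""
        load_extension(write_ext(tmp_path, text), host)
        ab = host.seqtypes.get("AB2")
        cm = configure_mode("abmode", ab, registry=host.modes,
                            properties=host.properties, seqtypes=host.seqtypes)
        vecs = run_engine([SequenceRecord(id="s", letters="AB")], ab, [cm])
        assert vecs[0].values == pytest.approx([4.0])  # (−1−1)²

    def test_wrong_dimension_is_data_fault_at_first_use(self, host, tmp_path, rng):
        text = """
def compute():
    emit_vector([1.0, 2.0])

register_mode("wrongdim", "PROT", 5, compute)
"""
        load_extension(write_ext(tmp_path, text), host)
        prot = host.seqtypes.get("PROT")
        cm = configure_mode("wrongdim", prot, registry=host.modes,
                            properties=host.properties, seqtypes=host.seqtypes)
        policy = FaultPolicy("skip")
        vecs = run_engine(random_records(prot, 1, rng), prot, [cm], policy)
        assert vecs == []
        assert "expected 5" in policy.reports[0][1]


class TestOptionsAndLabels:
    def test_declared_option_default_and_override(self, host, tmp_path):
        text = """
declare_option("-l", "int", 1, "lambda tiers")

def compute():
    lam = get_option("l")
    emit_vector([float(lam)])

register_mode("lamecho", "PROT", 1, compute)
"""
        load_extension(write_ext(tmp_path, text), host)
        assert host.option_value("l") == 1
        host.options["l"] = 10  # what CLI parsing does for "-l 10"
        prot = host.seqtypes.get("PROT")
        cm = configure_mode("lamecho", prot, registry=host.modes,
                            properties=host.properties, seqtypes=host.seqtypes)
        vecs = run_engine([SequenceRecord(id="s", letters="ACD")], prot, [cm])
        assert vecs[0].values == pytest.approx([10.0])

    def test_option_redeclaration_last_wins(self, host, tmp_path, capsys):
        load_extension(write_ext(tmp_path, 'declare_option("-l", "int", 1, "first")', "a.py"), host)
        load_extension(write_ext(tmp_path, 'declare_option("-l", "int", 5, "second")', "b.py"), host)
        assert host.option_value("l") == 5
        assert "re-declared" in capsys.readouterr().err

    def test_set_output_format(self, host, tmp_path):
        load_extension(write_ext(tmp_path, 'set_output_format("csv")'), host)
        assert host.output_format == "csv"
        with pytest.raises(ExtensionError, match="unknown output format"):
            load_extension(write_ext(tmp_path, 'set_output_format("xml")', "b.py"), host)

    def test_skip_sequence_and_set_label(self, host, tmp_path, rng):
        text = """
def compute():
    if seq_length() < 10:
        skip_sequence("too short for my mode")
    set_label(1)
    emit_vector([float(seq_length())])

register_mode("lenmode", "PROT", 1, compute)
"""
        load_extension(write_ext(tmp_path, text), host)
        prot = host.seqtypes.get("PROT")
        cm = configure_mode("lenmode", prot, registry=host.modes,
                            properties=host.properties, seqtypes=host.seqtypes)
        records = [
            SequenceRecord(id="long", letters="ACDEFGHIKLMNP"),
            SequenceRecord(id="short", letters="ACD"),
        ]
        policy = FaultPolicy("skip")
        vecs = run_engine(records, prot, [cm], policy)
        assert [v.seq_id for v in vecs] == ["long"]
        assert policy.reports == [("short", "too short for my mode")]
        assert host.labels == {"long": 1}


PSEAAC2_EXT = """
declare_option("-l", "int", 10, "lambda tiers")
declare_option("-w", "float", 0.05, "omega weight")

_pair = build_pair_tables(["hydrophobicity", "hydrophilicity"])

def compute():
    lam = get_option("l")
    omega = get_option("w")
    counts = kmer_counts(1)
    freqs = counts / counts.sum()
    taus = tau_series(lam, _pair)
    z = 1.0 + omega * taus.sum()
    import numpy as np
    emit_vector(np.concatenate([freqs / z, omega * taus / z]))

def dimension():
    return 20 + 2 * get_option("l")

register_mode("pseaac2-ext", "PROT", dimension, compute)
"""


class TestRoundTripFidelity:
    def test_extension_pseaac2_bit_identical_to_builtin(self, host, tmp_path, rng):
        """Type-2 pseudo-composition re-expressed through the extension API
        must reproduce the built-in mode exactly, bit for bit."""
        load_extension(write_ext(tmp_path, PSEAAC2_EXT), host)
        prot = host.seqtypes.get("PROT")
        records = random_records(prot, 100, rng, (15, 60))
        ext = configure_mode("pseaac2-ext", prot, registry=host.modes,
                             properties=host.properties, seqtypes=host.seqtypes)
        builtin = configure_mode("pseaac2", prot, registry=host.modes,
                                 properties=host.properties, seqtypes=host.seqtypes,
                                 lam=10, omega=0.05)
        ext_vecs = run_engine(records, prot, [ext])
        builtin_vecs = run_engine(records, prot, [builtin])
        assert len(ext_vecs) == len(builtin_vecs) == 100
        for a, b in zip(ext_vecs, builtin_vecs):
            assert np.array_equal(a.values, b.values)  # bit-identical
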