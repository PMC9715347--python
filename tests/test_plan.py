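"""Plan parsing, validation, canonical serialization, workspace packaging."""

import math

import numpy as np
import pytest

from conftest import make_plan, random_plan

from fedstar.aggregation import AggregatorRegistry
from fedstar.errors import IntegrityError, PlanParseError, PlanValidationError
from fedstar.plan import (
    export_workspace,
    import_workspace,
    parse_plan,
    serialize_plan,
    validate_plan,
)


class TestParse:
    def test_direct_field_mapping(self, plan_text):
        p = parse_plan(plan_text)
        assert p.rounds_to_train == 10
        assert list(p.tasks) == ["train", "validate"]
        assert len(p.collaborators) == 3
        assert p.aggregation.method == "weighted_mean"
        assert p.straggler.min_reporting_fraction == 0.5

    def test_missing_required_field_named(self, plan_text):
        text = plan_text.replace("rounds_to_train: 10\n", "")
        with pytest.raises(PlanValidationError, match="rounds_to_train"):
            parse_plan(text)

    def test_unknown_aggregation_method(self, plan_text):
        with pytest.raises(PlanValidationError, match="aggregation.method"):
            parse_plan(plan_text.replace("weighted_mean", "secret_sauce"))

    def test_custom_method_resolves_after_registration(self, plan_text):
        reg = AggregatorRegistry()
        reg.register("trimmed_mean", lambda g, rn=None: None)
        p = parse_plan(plan_text.replace("weighted_mean", "trimmed_mean"), registry=reg)
        assert p.aggregation.method == "trimmed_mean"

    def test_malformed_document_names_line(self):
        with pytest.raises(PlanParseError, match="line"):
            parse_plan("rounds_to_train: 10\n  bad_indent: [\n")

    def test_yaml_anchors_rejected(self):
        text = "rounds_to_train: &r 10\ntasks: *r\n"
        with pytest.raises(PlanParseError, match="anchor|alias"):
            parse_plan(text)

    def test_defaults_applied_only_where_permitted(self, plan_text):
        # drop the optional straggler/seed blocks: defaults kick in
        lines = [
            l
            for l in plan_text.splitlines()
            if not l.startswith(("straggler", "  min_reporting", "  round_cutoff", "seed"))
        ]
        p = parse_plan("\n".join(lines))
        assert p.straggler.min_reporting_fraction == 1.0
        assert math.isinf(p.straggler.round_cutoff)
        assert p.seed == 0


class TestValidate:
    def test_valid_plan_no_violations(self):
        assert validate_plan(make_plan()) == []

    def test_duplicate_collaborators(self):
        p = make_plan(collaborators=["site_a", "site_a"])
        v = validate_plan(p)
        assert len(v) == 1 and "unique" in v[0]

    def test_fraction_out_of_range(self):
        p = make_plan()
        p.straggler.min_reporting_fraction = 0
        v = validate_plan(p)
        assert any("min_reporting_fraction" in s for s in v)

    def test_train_task_required(self):
        p = make_plan()
        del p.tasks["train"]
        assert any("train" in s for s in validate_plan(p))

    @pytest.mark.parametrize(
        "mutate, field",
        [
            (lambda p: setattr(p, "rounds_to_train", 0), "rounds_to_train"),
            (lambda p: setattr(p, "collaborators", []), "collaborators"),
            (lambda p: setattr(p.tasks["train"], "epochs_per_round", 0), "epochs_per_round"),
            (lambda p: setattr(p.tasks["train"], "learning_rate", -1.0), "learning_rate"),
            (lambda p: setattr(p.tasks["train"], "batch_size", 0), "batch_size"),
            (lambda p: setattr(p.tasks["validate"], "metrics", []), "metrics"),
            (lambda p: setattr(p.network, "port", 0), "port"),
            (lambda p: setattr(p.straggler, "round_cutoff", 0), "round_cutoff"),
            (lambda p: setattr(p, "seed", -1), "seed"),
        ],
    )
    def test_out_of_range_fields_each_yield_violation(self, mutate, field):
        p = make_plan()
        mutate(p)
        v = validate_plan(p)
        assert v and any(field in s for s in v)


class TestSerialize:
    def test_roundtrip_identity(self):
        p = make_plan(min_fraction=0.5, cutoff=25.0)
        assert parse_plan(serialize_plan(p)) == p

    def test_canonical_fixed_point(self, plan_text):
        once = serialize_plan(parse_plan(plan_text))
        assert serialize_plan(parse_plan(once)) == once

    def test_seed_zero_explicit(self):
        assert "seed: 0" in serialize_plan(make_plan(seed=0))

    def test_invalid_plan_refused_with_violations(self):
        p = make_plan()
        p.rounds_to_train = 0
        with pytest.raises(PlanValidationError, match="rounds_to_train"):
            serialize_plan(p)

    def test_random_plan_roundtrip_property(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_plan(rng)
            assert parse_plan(serialize_plan(p)) == p


class TestWorkspace:
    @pytest.fixture
    def code_root(self, tmp_path):
        root = tmp_path / "code"
        (root / "src").mkdir(parents=True)
        (root / "src" / "task.py").write_text("def train():\n    pass\n")
        (root / "README.md").write_text("workspace readme\n")
        return root

    def test_export_deterministic(self, code_root):
        p = make_plan()
        assert export_workspace(p, code_root) == export_workspace(p, code_root)

    def test_roundtrip(self, code_root, tmp_path):
        p = make_plan()
        archive = export_workspace(p, code_root, requirements=["numpy>=1.20"])
        ws = import_workspace(archive, tmp_path / "dest")
        assert ws.plan == p
        assert ws.task_code_manifest == ["README.md", "src/task.py"]
        assert ws.requirements_manifest == ["numpy>=1.20"]
        assert (tmp_path / "dest" / "src" / "task.py").read_text() == (
            code_root / "src" / "task.py"
        ).read_text()

    def test_missing_manifest_file_named(self, code_root):
        with pytest.raises(FileNotFoundError, match="ghost.py"):
            export_workspace(make_plan(), code_root, manifest=["ghost.py"])

    def test_truncated_archive_leaves_nothing(self, code_root, tmp_path):
        archive = export_workspace(make_plan(), code_root)
        dest = tmp_path / "dest"
        with pytest.raises(IntegrityError):
            import_workspace(archive[: len(archive) // 2], dest)
        assert not dest.exists()

    def test_invalid_plan_inside_archive_materializes_nothing(self, code_root, tmp_path):
        p = make_plan()
        archive = export_workspace(p, code_root)
        # rebuild the archive with a corrupted plan by editing plan bytes
        import gzip
        import io
        import tarfile

        raw = gzip.decompress(archive)
        buf = io.BytesIO()
        with tarfile.open(fileobj=io.BytesIO(raw)) as src, tarfile.open(
            fileobj=buf, mode="w"
        ) as dst:
            for m in src.getmembers():
                data = src.extractfile(m).read()
                if m.name == "plan.yaml":
                    data = data.replace(b"rounds_to_train: 3", b"rounds_to_train: 0")
                    m.size = len(data)
                dst.addfile(m, io.BytesIO(data))
        bad = gzip.compress(buf.getvalue())
        dest = tmp_path / "dest2"
        with pytest.raises(PlanValidationError):
            import_workspace(bad, dest)
        assert not dest.exists()
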