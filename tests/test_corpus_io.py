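from datetime import datetime, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postmine import (
    MaskingRules,
    Post,
    anonymize,
    read_posts,
    read_reference_document,
    write_posts,
)
from postmine.corpus_io import ConfigurationError, InputError, RowError

from conftest import make_post


HEADER = "post_id\ttype\tmessage\tcreated_time\tlikes_count\tcomments_count\tshares_count\treactions_count\n"


def write_table(path, rows):
    path.write_text(HEADER + "".join(r + "\n" for r in rows), encoding="utf-8")


class TestReadPosts:
    def test_row_count_preserved(self, tmp_path):
        rows = [
            f"p{i}\tstatus\thola\t2018-03-01T1{i}:00:00+01:00\t1\t2\t0\t1"
            for i in range(5)
        ]
        path = tmp_path / "posts.tsv"
        write_table(path, rows)
        posts = read_posts(path)
        assert len(posts) == 5
        assert [p.post_id for p in posts] == [f"p{i}" for i in range(5)]

    def test_reactions_below_likes_rejected_strict(self, tmp_path):
        path = tmp_path / "posts.tsv"
        write_table(path, ["p1\tstatus\thola\t2018-03-01T10:00:00\t5\t0\t0\t3"])
        with pytest.raises(RowError, match="row 2"):
            read_posts(path)

    def test_lenient_mode_skips_bad_rows(self, tmp_path):
        path = tmp_path / "posts.tsv"
        write_table(
            path,
            [
                "p1\tstatus\tok\t2018-03-01T10:00:00\t1\t0\t0\t1",
                "p2\tstatus\tbad\t2018-03-01T10:00:00\t5\t0\t0\t3",
                "p3\tstatus\tbad ts\tnot-a-date\t1\t0\t0\t1",
                "p4\tlink\tok\t2018-03-01T11:00:00\t0\t0\t0\t0",
            ],
        )
        posts = read_posts(path, lenient=True)
        assert [p.post_id for p in posts] == ["p1", "p4"]

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "posts.tsv"
        path.write_text("post_id\ttype\tmessage\n", encoding="utf-8")
        with pytest.raises(ConfigurationError, match="created_time"):
            read_posts(path)

    def test_naive_timestamps_get_configured_zone(self, tmp_path):
        path = tmp_path / "posts.tsv"
        write_table(path, ["p1\tstatus\thola\t2018-03-01T10:00:00\t0\t0\t0\t0"])
        (post,) = read_posts(path)
        assert post.created.tzinfo is not None
        assert post.created.utcoffset() is not None

    def test_roundtrip_preserves_all_fields(self, tmp_path):
        posts = [
            make_post(
                post_id=f"p{i}",
                post_type=t,
                message=m,
                created=datetime(2018, 3, 1 + i, 13, 30, tzinfo=timezone.utc),
                likes=i,
                comments=2 * i,
                shares=i % 2,
                reactions=i + 1,
            )
            for i, (t, m) in enumerate(
                [("status", "hola qué tal"), ("photo", "después de todo"), ("link", "")]
            )
        ]
        path = tmp_path / "roundtrip.tsv"
        write_posts(posts, path)
        assert read_posts(path) == posts


class TestReferenceDocument:
    def test_text_returned_unchanged(self, tmp_path):
        path = tmp_path / "ref.txt"
        text = "línea uno\nlínea dos\nlínea tres\n"
        path.write_text(text, encoding="utf-8")
        assert read_reference_document(path) == text

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("  \n", encoding="utf-8")
        with pytest.raises(InputError):
            read_reference_document(path)

    def test_accented_characters_preserved(self, tmp_path):
        path = tmp_path / "ref.txt"
        text = "atención diagnóstico después síndrome año\n"
        path.write_text(text, encoding="utf-8")
        assert read_reference_document(path) == text


class TestAnonymize:
    def test_email_masked(self):
        posts = [make_post(message="write to ana@example.org please")]
        (out,) = anonymize(posts)
        assert out.message == "write to <EMAIL> please"

    def test_names_masked_case_insensitive(self):
        rules = MaskingRules(names=["Ana García"])
        posts = [make_post(message="gracias ana garcía por todo")]
        (out,) = anonymize(posts, rules)
        assert out.message == "gracias <NAME> por todo"

    def test_message_without_identifiers_unchanged(self):
        posts = [make_post(message="el síndrome de marfan")]
        assert anonymize(posts)[0].message == "el síndrome de marfan"

    def test_non_message_fields_untouched(self):
        post = make_post(message="ana@example.org", likes=3, comments=2, reactions=5)
        (out,) = anonymize([post], MaskingRules(names=["ana"]))
        assert (out.likes, out.comments, out.reactions) == (3, 2, 5)
        assert out.created == post.created and out.post_type == post.post_type

    @settings(deadline=None, max_examples=50)
    @given(
        st.text(
            alphabet=st.characters(whitelist_categories=("L", "Zs", "P")), max_size=80
        ),
        st.lists(st.sampled_from(["ana", "juan", "maría lópez"]), max_size=2),
    )
    def test_idempotent(self, message, names):
        rules = MaskingRules(names=names)
        once = anonymize([make_post(message=message)], rules)
        twice = anonymize(once, rules)
        assert [p.message for p in twice] == [p.message for p in once]


class TestPostInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"likes": -1},
            {"comments": -2},
            {"likes": 5, "reactions": 3},
            {"post_type": "story"},
        ],
    )
    def test_invalid_posts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_post(**kwargs)

    def test_naive_timestamp_rejected(self):
        with pytest.raises(ValueError, match="timezone"):
            make_post(created=datetime(2018, 3, 1, 12, 0))
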