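from datetime import datetime, timezone

import pytest

from postmine import Post


def make_post(
    post_id="p1",
    post_type="status",
    message="",
    created=None,
    likes=0,
    comments=0,
    shares=0,
    reactions=None,
):
    """Post factory; reactions defaults to likes (no extra reactions)."""
    if created is None:
        created = datetime(2018, 3, 1, 12, 0, tzinfo=timezone.utc)
    if reactions is None:
        reactions = likes
    return Post(
        post_id=post_id,
        post_type=post_type,
        message=message,
        created=created,
        likes=likes,
        comments=comments,
        shares=shares,
        reactions=reactions,
    )


@pytest.fixture
def post_factory():
    return make_post
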