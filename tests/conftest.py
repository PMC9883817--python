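import pandas as pd
import pytest

from stressquad.extraction import StressLexicon


@pytest.fixture(scope="session")
def lexicon() -> StressLexicon:
    return StressLexicon.default()


def make_reviews(rows):
    """Build a review table from (company_id, date, rating, text) tuples."""
    return pd.DataFrame(rows, columns=["company_id", "date", "rating", "text"])


@pytest.fixture
def reviews_builder():
    return make_reviews
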