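"""Sub-Saharan African country -> region mapping.

Regions follow the 2015 Global Burden of Disease classification with two
amendments used throughout this package: Western and Central Africa are
pooled into a single "Western/Central Africa" analysis region (few surveys
are available in either), and Mauritius is coded as an Eastern African
country.
"""

from __future__ import annotations

WESTERN_CENTRAL = "Western/Central Africa"
EASTERN = "Eastern Africa"
SOUTHERN = "Southern Africa"

REGIONS = (WESTERN_CENTRAL, EASTERN, SOUTHERN)

#: ISO3 -> analysis region for the 48 sub-Saharan African countries.
COUNTRY_REGION: dict[str, str] = {
    # GBD Western sub-Saharan Africa
    "BEN": WESTERN_CENTRAL, "BFA": WESTERN_CENTRAL, "CPV": WESTERN_CENTRAL,
    "CIV": WESTERN_CENTRAL, "GMB": WESTERN_CENTRAL, "GHA": WESTERN_CENTRAL,
    "GIN": WESTERN_CENTRAL, "GNB": WESTERN_CENTRAL, "LBR": WESTERN_CENTRAL,
    "MLI": WESTERN_CENTRAL, "MRT": WESTERN_CENTRAL, "NER": WESTERN_CENTRAL,
    "NGA": WESTERN_CENTRAL, "SEN": WESTERN_CENTRAL, "SLE": WESTERN_CENTRAL,
    "STP": WESTERN_CENTRAL, "TGO": WESTERN_CENTRAL,
    # GBD Central sub-Saharan Africa (pooled with Western)
    "AGO": WESTERN_CENTRAL, "CMR": WESTERN_CENTRAL, "CAF": WESTERN_CENTRAL,
    "TCD": WESTERN_CENTRAL, "COG": WESTERN_CENTRAL, "COD": WESTERN_CENTRAL,
    "GNQ": WESTERN_CENTRAL, "GAB": WESTERN_CENTRAL,
    # GBD Eastern sub-Saharan Africa (Mauritius amended in)
    "BDI": EASTERN, "COM": EASTERN, "DJI": EASTERN, "ERI": EASTERN,
    "ETH": EASTERN, "KEN": EASTERN, "MDG": EASTERN, "MWI": EASTERN,
    "MUS": EASTERN, "MOZ": EASTERN, "RWA": EASTERN, "SYC": EASTERN,
    "SOM": EASTERN, "SSD": EASTERN, "TZA": EASTERN, "UGA": EASTERN,
    "ZMB": EASTERN,
    # GBD Southern sub-Saharan Africa
    "BWA": SOUTHERN, "SWZ": SOUTHERN, "LSO": SOUTHERN, "NAM": SOUTHERN,
    "ZAF": SOUTHERN, "ZWE": SOUTHERN,
}

#: common English names and variants -> ISO3
COUNTRY_ALIASES: dict[str, str] = {
    "benin": "BEN", "burkina faso": "BFA", "cabo verde": "CPV",
    "cape verde": "CPV", "cote d'ivoire": "CIV", "côte d'ivoire": "CIV",
    "ivory coast": "CIV", "gambia": "GMB", "the gambia": "GMB",
    "ghana": "GHA", "guinea": "GIN", "guinea-bissau": "GNB",
    "liberia": "LBR", "mali": "MLI", "mauritania": "MRT", "niger": "NER",
    "nigeria": "NGA", "senegal": "SEN", "sierra leone": "SLE",
    "sao tome and principe": "STP", "são tomé and príncipe": "STP",
    "togo": "TGO", "angola": "AGO", "cameroon": "CMR",
    "central african republic": "CAF", "chad": "TCD", "congo": "COG",
    "republic of the congo": "COG", "democratic republic of the congo": "COD",
    "dr congo": "COD", "drc": "COD", "equatorial guinea": "GNQ",
    "gabon": "GAB", "burundi": "BDI", "comoros": "COM", "djibouti": "DJI",
    "eritrea": "ERI", "ethiopia": "ETH", "kenya": "KEN", "madagascar": "MDG",
    "malawi": "MWI", "mauritius": "MUS", "mozambique": "MOZ",
    "rwanda": "RWA", "seychelles": "SYC", "somalia": "SOM",
    "south sudan": "SSD", "tanzania": "TZA",
    "united republic of tanzania": "TZA", "uganda": "UGA", "zambia": "ZMB",
    "botswana": "BWA", "eswatini": "SWZ", "swaziland": "SWZ",
    "lesotho": "LSO", "namibia": "NAM", "south africa": "ZAF",
    "zimbabwe": "ZWE",
}


class UnknownCountryError(KeyError):
    """Raised when a country is not in the packaged sub-Saharan Africa table."""


def normalize_country(country: str) -> str:
    """Return the ISO3 code for an ISO3 code or a common English name."""
    c = country.strip()
    if c.upper() in COUNTRY_REGION:
        return c.upper()
    iso3 = COUNTRY_ALIASES.get(c.lower())
    if iso3 is None:
        raise UnknownCountryError(
            f"unknown sub-Saharan African country: {country!r}"
        )
    return iso3


def map_country_to_region(country: str) -> str:
    """Map an ISO3 code or country name to its analysis region.

    Returns one of ``Western/Central Africa``, ``Eastern Africa`` or
    ``Southern Africa``.
    """
    return COUNTRY_REGION[normalize_country(country)]
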