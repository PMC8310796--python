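"""Shared unit and window constants.

Ages are handled internally in days; a year is 365.25 days throughout.
The eligibility / AR-search window is 18 months to 13 years, inclusive.
"""

DAYS_PER_YEAR = 365.25

#: 18 months and 13 years expressed in days (548, 4748); both bounds inclusive.
ELIGIBILITY_WINDOW_DAYS = (548.0, 4748.0)
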