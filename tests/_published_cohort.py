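"""Published 12-subject cohort summary used as a regression fixture.

Rows: (subject, group, sleep_start, sleep_onset, sleep_end,
time_in_bed_min, sleep_latency_min, tst_min).

Two cells of the published table conflict with their own clock times and
the stated TST = TIB - SL identity; for those rows the values implied by
the clock times are used instead:

* INS6 — published TST 460, but 528.0 - 19.5 = 508.5, and the row's
  published WASO (456) plus a TST of 460 would exceed its TIB (528);
* n11 — published TIB 573 and onset 22:15:03 duplicate row n1's values
  and contradict the row's own start/end times (22:37:16 -> 7:23:16 =
  526 min); its published SL 18 and TST 508 do satisfy 526 - 18 = 508,
  giving the onset 22:55:16 used here.
"""

TABLE1 = [
    ("INS2", "insomnia", "18:25:37", "23:11:38", "08:22:38", 837.02, 286.02, 551.0),
    ("INS4", "insomnia", "21:34:04", "21:47:34", "03:40:04", 366.0, 13.5, 352.5),
    ("INS5", "insomnia", "17:58:48", "23:30:18", "08:18:18", 859.5, 331.5, 528.0),
    ("INS6", "insomnia", "22:37:17", "22:56:47", "07:25:17", 528.0, 19.5, 508.5),
    ("INS7", "insomnia", "19:58:14", "21:54:44", "08:19:14", 741.0, 116.5, 624.5),
    ("INS8", "insomnia", "22:43:04", "23:14:34", "05:42:34", 419.5, 31.5, 388.0),
    ("n1", "healthy", "22:09:33", "22:15:03", "07:42:33", 573.0, 5.5, 567.5),
    ("n2", "healthy", "22:19:06", "22:23:06", "06:38:36", 499.5, 4.0, 495.5),
    ("n3", "healthy", "23:06:12", "23:07:12", "07:26:12", 500.0, 1.0, 499.0),
    ("n5", "healthy", "22:49:48", "22:51:48", "07:13:18", 503.5, 2.0, 501.5),
    ("n10", "healthy", "23:24:52", "23:56:22", "06:34:22", 429.5, 31.5, 398.0),
    ("n11", "healthy", "22:37:16", "22:55:16", "07:23:16", 526.0, 18.0, 508.0),
]
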