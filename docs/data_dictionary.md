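# Data dictionary

All files are UTF-8, comma-delimited, one header row, no index column.
Masses in grams, contents in g/kg.

## birds.csv — one row per hen

| column          | unit  | meaning                                              |
|-----------------|-------|------------------------------------------------------|
| bird_id         | —     | unique opaque identifier                             |
| line            | —     | genetic line label (e.g. A, B)                       |
| dfc             | g/day | mean daily feed consumed over the recording period   |
| dmw             | g/day | mean daily fresh manure weight (collection total / collection days) |
| dbw             | g     | mean body weight                                     |
| eggs_laid       | count | eggs collected over the expectation window           |
| mean_egg_weight | g     | mean weight per egg; empty if no eggs laid           |
| expected_eggs   | count | laying-percentage denominator (default 8)            |
| period_days     | days  | feed-recording window used for FCR (default 7)       |

## assays.csv — one row per hen's pooled manure sample

| column       | unit            | meaning                                        |
|--------------|-----------------|------------------------------------------------|
| bird_id      | —               | matches birds.csv                              |
| adm          | g/kg fresh      | air-dry recovery: air-dried mass per kg fresh manure |
| dm_ad        | g/kg air-dried  | dry matter of the air-dried sample             |
| ash_ad       | g/kg air-dried  | ash content                                    |
| nitrogen_ad  | g/kg air-dried  | total nitrogen (Dumas)                         |
| fat_ad       | g/kg air-dried  | fat after hydrochloric-acid hydrolysis         |
| uric_acid_ad | g/kg air-dried  | uric acid                                      |

## feed.csv — exactly one row

| column   | unit        | meaning                                  |
|----------|-------------|------------------------------------------|
| dm       | g/kg as-fed | dry matter                               |
| nitrogen | g/kg as-fed | total nitrogen                           |
| fat      | g/kg as-fed | crude fat                                |
| ash      | g/kg as-fed | crude ash                                |
| sugar    | g/kg as-fed | sugar; optional, unused by the DC chain  |

## ground_truth.csv — written by the simulator

bird_id, line, the four latent digestibility coefficients
(`true_dc_dm`, `true_dc_fat`, `true_dc_n`, `true_dc_org`, percent),
`excreted_dm` (g/day) and `moisture_frac` of fresh manure.
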