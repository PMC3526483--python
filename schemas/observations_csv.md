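# Observations CSV

Long-format observation table, UTF-8, comma-separated, header required.
One row per binomial trial or per rank-task score.

| column      | type    | rule                                                         |
|-------------|---------|--------------------------------------------------------------|
| subject_id  | string  | must exist in the accompanying study design                  |
| species     | string  | must match the design's species for that subject             |
| task_id     | string  | must exist in the design                                     |
| trial_index | integer | 0-based; required for binomial tasks; `0 <= i < n_trials`    |
| outcome     | 0 or 1  | required for binomial tasks, empty otherwise                 |
| score       | float   | required for rank tasks (full precision), empty otherwise    |

Exactly one of `outcome` / `score` is non-empty per row.  Duplicate
(subject, task, trial) or (subject, task) score rows are errors.  The set
of (subject, task) pairs present defines the dataset's participation.
Parse errors report the offending 1-based file row.
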