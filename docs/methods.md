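# Methods

`clinicflow` is a terminating discrete-event simulation of one
symptomatic breast clinic.  One trial simulates 64 weeks of continuous
calendar time (12 warm-up + 52 collection) on a minute clock whose zero
is a Monday 00:00; all outputs are means with 95% t-intervals over 150
independent replications unless stated otherwise.

## Patient generation

GP presentations form a homogeneous Poisson process with expected total
`annual_volume × demand_multiplier` per 52 weeks (default 10,542/year,
the clinic's 2019 referral volume).  An alternative "windowed" mode
reproduces the audit bookkeeping convention — exponential inter-arrival
times with mean 16.2778 min confined to a ~55 h weekly arrival window —
which has the same weekly expectation; all shipped analyses use the
calendar mode, since every outcome depends on weekly volume, not the
clock convention.

Cancer status is Bernoulli(0.0476), independent across patients.  Every
clinic attender starts with an initial assessment; 25% of non-cancer
patients are discharged there.  The rest draw one of nine diagnostic
sequences (mammogram/ultrasound/biopsy combinations) from the
audit-derived frequency table for their stratum.  Two global rules
apply: sequences containing both imaging modalities run mammogram-first
with probability 0.60, and cancer patients always end with exactly one
biopsy (appended if the drawn sequence lacks it — the audit's ~8% of
cancer cases without a recorded biopsy are treated as data artefacts,
per clinical practice).

Service times (minutes): initial assessment 10, mammogram 20, ultrasound
20, each drawn from a symmetric triangular distribution with the stated
value as mode/median and a ±25% relative half-width (the half-width is
configurable; zero gives exact durations, used by the oracle tests).
Biopsy is the stated two-point 30/45 mixture with equal weights, its
patient preparation folded in.  Imaging carries a separate 5-minute
preparation step (not separately documented for this clinic; the value
sits inside the calibration described below).

## Triage

Standard care refers everyone at presentation.  Under the test arm a
patient's result is high-risk with probability = sensitivity (cancer) or
1 − specificity (non-cancer); defaults 0.98/0.20.  High risk → immediate
referral.  Low risk → GP override (immediate) with the configured
probability; otherwise a delayed referral exactly 6 weeks later with the
stratum's return probability, else no referral.  Draws are independent
Bernoulli; test turnaround is zero by default (the blood test is taken
around the time of the referral decision).  The closed-form referral
fractions (`referral_fraction_closed_form`) serve as the analytic oracle
for the simulated fractions.

## Booking and the weekly schedule

Eight half-day sessions per week (Mon/Tue/Wed/Thu/Fri; AM 09:00–13:00,
PM 14:00–18:00): seven "full" clinics and the small Tue AM "add-on".
Referred patients wait in a single FIFO queue.  Two conventions here are
reconstructions of operational detail that is not publicly documented,
fixed against the clinic's externally validated 2019 figures and then
frozen:

* **Booking notice.** A patient referred on day *d* can attend sessions
  from day *d* + 7 (same weekday the following week) — the
  referral-to-appointment logistics floor.  Without it an uncongested
  clinic would see patients in ~1–2 days, which no NHS audit shows; with
  it the uncongested arms settle at ~7.9 calendar days to clinic.
  Overspill returners are exempt (they are re-admitted from the next
  calendar day).
* **Responsive booking phase.** Full clinics book 25 new patients; the
  booking rises by 1 per 15 patients of backlog, reaching its first
  increment just above the 380 threshold (at 385) and capping at 34.
  The backlog that drives the rule counts every referred-but-not-yet-
  seen patient.  The threshold anchors to "slightly above two weeks of
  base capacity" (2 × 185 = 370), and the onset phase within the first
  15-patient step is set so the simulated standard-care arm reproduces
  the NHS-reported 66.5% TWW attainment for the region (we obtain 67.6
  ± 0.3%); the stepping phase is exposed as `BookingRule.first_boost_at`.

The add-on clinic always books 10.  Each session additionally admits up
to 5 (full) / 6 (add-on) patients from the clinic-returns queue, FIFO;
unused return slots are never converted to new-patient slots.  Session
capacity is evaluated from the backlog at the session's start instant.

## Inside a session

All booked patients are present at the session start (returns first —
they have waited longest).  Each activity seizes one room (4 assessment,
3 mammogram, 4 ultrasound, 4 biopsy) plus eligible staff:

| activity | staff seized (seize order) |
|---|---|
| initial assessment | PA → NP → consultant |
| mammogram | band-6 non-sono → band-6 sono → band-7 sono |
| ultrasound | band-6 sono → band-7 sono |
| biopsy | consultant **and** grade-2 → band-6 (either) |
| imaging prep | grade-2 → band-6 non-sono → band-6 sono |

The seize order conserves the scarcest staff (sonographers for
ultrasound, consultants for biopsy) and is configurable in spirit: the
eligibility sets live in one table.  Patients are not pinned to a staff
member.  Mammogram and ultrasound run as an atomic prep → image
subprocess: prep starts only when an imaging room is free, the room is
held from prep start, and the patient may wait (room in hand) for
imaging staff.  Dispatch scans waiting patients in queue-entry order, so
FIFO holds within each activity queue; room-holding post-prep patients
get released staff first, since they entered service earliest.

Sessions last 240 minutes.  New activities may start up to the closing
instant; started work always completes — with mean durations ≤ 45 min
the 15-minute overtime allowance is modelled as permissive for in-flight
work rather than as a hard truncation that would strand patients
mid-procedure.  Patients still queueing at close are routed to the
clinic-returns queue with their remaining sequence preserved; each such
routing is one *overspill appointment*.

**Staffing.** Per-session staff counts (full clinic: 2 consultants,
1 NP, 1 PA, 2 band-7 sonographers, 1 band-6 sonographer, 1 band-6
non-sonographer, 2 grade-2 assistants; add-on clinic: one of each) are
thinned by an availability fraction representing time lost to admin and
follow-up work.  The fractional part of `count × availability` is
resolved by a per-session Bernoulli draw (long-run mean preserved); a
floor mode is available.  The availability default, **0.805**, is the
one fitted quantity in the package: coordinate bisection (20-trial
evaluations, common random numbers, deterministic given the seed) on the
absolute difference between the simulated standard-care annual overspill
and the clinic's 2019 audit count of 1,664.  `calibrate_roster` exposes
the procedure (tunables: availability fractions, prep duration) and
reports non-convergence rather than accepting a poor fit.

## Outcomes

Computed over exits within the 52-week collection window ("completing
the model" = exiting by any route: full diagnostics, discharge after
assessment, or never referred):

* **TWW target**: fraction of referred-and-seen patients whose first
  clinic date is within 14 calendar days of their initial GP
  presentation (date difference ≤ 14).  The clock runs from
  presentation, so a 6-week delayed returner always misses the target —
  this is what makes the cancer stratum's TWW equal 100% minus its
  delayed share, as observed.
* **Time to clinic**: mean Mon–Fri weekdays from presentation date to
  first clinic date (weekdays strictly after the start date, through the
  clinic date).
* **Overspill appointments**: overspill routings in the window.
* Completion counts and referral/delay fractions per cancer stratum.

95% intervals across trials are t-based (normal approximation
available).  Per-trial seeds derive from
`SeedSequence(master, crc32(strategy), trial)`; a shared label pairs
streams across strategies (common random numbers, off by default).

## What the generator does and does not emulate

The synthetic population reproduces the clinic's volume, prevalence,
pathway mix and service-time medians, which is what the booking and
capacity dynamics need.  It does not model symptom type, age, tumour
stage, screening-detected disease, seasonal or weekday demand patterns,
DNA (non-attendance), staggered within-session arrival, or correlation
between GP override and severity.  Passing tests therefore demonstrate
the *capacity* consequences of triage under stationary demand, not
patient-level clinical outcomes.

## Known limitations

* The two operational reconstructions (notice floor, booking phase) are
  anchored to external validation figures; other choices reproduce the
  uncongested or the congested arms, but not both.
* Removing the small Tue AM clinic raises simulated overspill by ~7%
  (952/year), a much smoother response than the ~46% jump in the
  reference figures used for acceptance testing; the roster/booking
  detail needed to sharpen that nonlinearity is not publicly available.
  Relatedly, the Wed-AM-removal arm collapses to ~8% TWW here versus
  ~3% in those reference figures — the collapse is reproduced, its
  depth is not.
* Staff availability is thinned capacity, not scheduled breaks; MDT and
  diagnosis exits are instantaneous and unresourced; health-economic
  outcomes are out of scope.
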