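analysis
approach
article
assay
assessment
association
authors
baseline
benefit
between
biology
burden
candidate
capacity
clinical
cohort
collection
common
community
comparison
complete
component
condition
confirm
consistent
context
control
correlation
cohesive
criteria
current
decrease
describe
design
detail
detection
development
difference
discussion
distribution
dynamic
early
effect
efficacy
elevated
evidence
examine
exposure
expression
factor
feature
figure
finding
follow
framework
frequency
function
further
general
global
group
growth
health
higher
hospital
human
immune
impact
important
improve
incidence
increase
indicate
infection
inflammation
influence
information
initial
intervention
investigation
laboratory
larger
level
limitation
literature
longitudinal
lower
majority
measure
mechanism
median
medical
method
model
moderate
molecular
monitor
mortality
multiple
national
network
normal
novel
observation
outcome
overall
paper
parameter
participant
pathway
patient
pattern
period
population
positive
potential
practice
present
prevalence
previous
primary
process
profile
progression
protocol
public
quality
random
range
rapid
recent
recovery
reduction
region
regression
related
report
research
response
result
review
risk
sample
screening
secondary
sequence
series
severe
severity
signal
significant
similar
single
source
specific
spectrum
stage
standard
statistical
strategy
structure
subject
summary
support
surveillance
survey
symptom
system
table
target
testing
therapy
tissue
total
treatment
trial
understanding
unique
update
validation
value
variable
variation
vector
weekly
wider
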