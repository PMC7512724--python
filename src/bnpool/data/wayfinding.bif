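network wayfinding {
}
variable Communication {
  type discrete [ 2 ] { Effective, Ineffective };
}
variable "Environmental Factors" {
  type discrete [ 2 ] { Good, Bad };
}
variable "Human Factors" {
  type discrete [ 2 ] { Good, Bad };
}
variable "Navigation Pathway" {
  type discrete [ 2 ] { Simple, Complex };
}
variable "Visual Elements of Communication" {
  type discrete [ 2 ] { Good, Bad };
}
variable Wayfinding {
  type discrete [ 2 ] { Effective, Ineffective };
}
probability ( Communication | "Visual Elements of Communication" ) {
  ( Good ) 0.87, 0.13;
  ( Bad ) 0.45000000000000001, 0.55000000000000004;
}
probability ( "Environmental Factors" | "Navigation Pathway" ) {
  ( Simple ) 0.85999999999999999, 0.14000000000000001;
  ( Complex ) 0.55000000000000004, 0.45000000000000001;
}
probability ( "Human Factors" ) {
  table 0.80000000000000004, 0.20000000000000001;
}
probability ( "Navigation Pathway" ) {
  table 0.68999999999999995, 0.31;
}
probability ( "Visual Elements of Communication" ) {
  table 0.70999999999999996, 0.28999999999999998;
}
probability ( Wayfinding | "Human Factors", "Environmental Factors", Communication ) {
  ( Good, Good, Effective ) 0.94999999999999996, 0.050000000000000003;
  ( Good, Good, Ineffective ) 0.80000000000000004, 0.20000000000000001;
  ( Good, Bad, Effective ) 0.78000000000000003, 0.22;
  ( Good, Bad, Ineffective ) 0.55000000000000004, 0.45000000000000001;
  ( Bad, Good, Effective ) 0.59999999999999998, 0.40000000000000002;
  ( Bad, Good, Ineffective ) 0.40000000000000002, 0.59999999999999998;
  ( Bad, Bad, Effective ) 0.34999999999999998, 0.65000000000000002;
  ( Bad, Bad, Ineffective ) 0.10000000000000001, 0.90000000000000002;
}
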