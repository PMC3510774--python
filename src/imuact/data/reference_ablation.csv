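class,accel_only,accel_gyro
C1,89.6,94.1
C2,85.8,92.0
C3,78.0,90.1
C4,85.4,91.7
C5,100.0,100.0
C6,65.6,69.8
C7,66.0,79.4
C8,64.8,70.4
C9,49.2,52.3
weighted_average,83.7,90.2
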