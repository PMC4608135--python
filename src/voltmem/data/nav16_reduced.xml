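<?xml version="1.0" encoding="UTF-8"?>
<!-- Reduced persistent Nav1.6 kinetics: a single fast activation gate with
     Boltzmann steady state (half-activation -17 mV, steepness 0.1565 /mV)
     and a constant 1 ms relaxation time.  No inactivation gate, so the
     channel is persistent. -->
<channelml units="Physiological Units">
  <channel_type name="nav16_reduced">
    <current_voltage_relation cond_law="ohmic" ion="Na">
      <q10_settings q10_factor="3" experimental_temp="23"/>
      <gate name="m" instances="1" role="activation">
        <steady_state expr_form="sigmoid" midpoint="-17" slope="0.1565"/>
        <time_course expr_form="constant" tau="1.0"/>
      </gate>
    </current_voltage_relation>
  </channel_type>
</channelml>
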