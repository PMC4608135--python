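<?xml version="1.0" encoding="UTF-8"?>
<!-- SYNTHETIC slow hyperpolarization-activated sodium-conducting channel,
     engineered to demonstrate attractor overshoot: its 200 ms gate stays
     open long after release from a hyperpolarizing clamp, driving the
     voltage past the nearest attractor. -->
<channelml units="Physiological Units">
  <channel_type name="slow_inward_synthetic">
    <current_voltage_relation cond_law="ohmic" ion="Na">
      <q10_settings q10_factor="3" experimental_temp="36"/>
      <gate name="s" instances="1" role="activation">
        <steady_state expr_form="sigmoid" midpoint="-110" slope="-0.2"/>
        <time_course expr_form="constant" tau="200.0"/>
      </gate>
    </current_voltage_relation>
  </channel_type>
</channelml>
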