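{% extends "base.html" %}
{% block title %}Specific name index{% endblock %}
{% block heading %}Specific name index{% endblock %}
{% block content %}
<ul class="specific-index">
{% for entry in entries %}
  <li><a href="{{ links.specific(entry.epithet) }}"><em>{{ entry.epithet }}</em></a></li>
{% endfor %}
</ul>
{% endblock %}
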